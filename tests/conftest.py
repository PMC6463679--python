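from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cagesel import pipeline, synthetic_data
from cagesel.clustering import TagCluster


def make_cluster(ctss: dict[int, int], strand: str = "+", chrom: str = "chr1",
                 tag_length: int = 27) -> TagCluster:
    """Build a TagCluster directly from a position->count map."""
    positions = np.array(sorted(ctss), dtype=np.int64)
    counts = np.array([ctss[p] for p in sorted(ctss)], dtype=np.int64)
    if strand == "+":
        start, end = int(positions.min()), int(positions.max()) + tag_length - 1
    else:
        start, end = int(positions.min()) - tag_length + 1, int(positions.max())
    return TagCluster(chrom=chrom, strand=strand, start=start, end=end,
                      positions=positions, counts=counts)


@pytest.fixture
def ctss_frame():
    def _build(rows: list[tuple]) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return _build


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete simulated dataset shared across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    cfg = synthetic_data.scaled_config(seed=11, n_genes=300, library_size=60_000)
    return synthetic_data.simulate(cfg, out)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline outputs on the small simulated dataset."""
    out_dir = tmp_path_factory.mktemp("run_small")
    cfg = pipeline.RunConfig(
        ctss_translatome=small_bundle.ctss_translatome,
        ctss_transcriptome=small_bundle.ctss_transcriptome,
        gtf=small_bundle.gtf, fasta=small_bundle.fasta,
        out_dir=str(out_dir), group_k=20, seed=5)
    tables = pipeline.run_all(cfg)
    return cfg, tables
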