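"""Shared paths and configuration for the numbered analysis scripts.

The analysis runs on a mid-sized simulated dataset (1500 genes, 3e5 tags
per condition) so every script finishes in seconds; bulky intermediate
data lives under scratch/ while the summary tables land in
results/analysis/.
"""

from __future__ import annotations

import os

import pandas as pd

from cagesel import pipeline, synthetic_data as sd

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SIM_DIR = os.path.join(ROOT, "scratch", "analysis_sim")
OUT_DIR = os.path.join(SIM_DIR, "out")
RESULTS = os.path.join(ROOT, "results", "analysis")

SIM_CONFIG = sd.scaled_config(seed=1, n_genes=1500, library_size=300_000)


def sim_paths() -> dict[str, str]:
    return {
        "fasta": os.path.join(SIM_DIR, "genome.fa"),
        "gtf": os.path.join(SIM_DIR, "annotation.gtf"),
        "ctss_translatome": os.path.join(SIM_DIR, "translatome.ctss.tsv"),
        "ctss_transcriptome": os.path.join(SIM_DIR, "transcriptome.ctss.tsv"),
    }


def run_config(**overrides) -> pipeline.RunConfig:
    paths = sim_paths()
    for name, path in paths.items():
        if not os.path.exists(path):
            raise SystemExit(f"missing {path}; run analysis/01_simulate.py first")
    cfg = pipeline.RunConfig(out_dir=OUT_DIR, group_k=100, seed=1, **paths)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def load_bundle() -> sd.SimBundle:
    """Rebuild the SimBundle (with truth key) from the simulation directory."""
    paths = sim_paths()
    tc_truth = pd.read_csv(os.path.join(SIM_DIR, "truth_tc.tsv"), sep="\t")
    gene_truth = pd.read_csv(os.path.join(SIM_DIR, "truth_gene.tsv"), sep="\t")
    from cagesel.io_cage import read_fasta
    genome_length = read_fasta(paths["fasta"]).total_length
    return sd.SimBundle(paths["fasta"], paths["gtf"],
                        paths["ctss_translatome"], paths["ctss_transcriptome"],
                        tc_truth, gene_truth, genome_length)


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
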