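"""Tag clustering with a Poisson background significance rule.

CAGE tags are 27-nt reads whose 5' end marks a TSS.  Tags on the same
strand whose bodies overlap by at least one nucleotide are merged
(single-linkage) into a tag set; any set with at least ``min_tags`` tags is
kept as a tag cluster (TC), the unit treated as a putative core promoter.

The ``min_tags`` default of 4 is justified by a Poisson background model:
if T uniquely mapped tags fell uniformly on a genome of length N, the
number of tags landing in a tag-set window of (n-1)*27 nt is Poisson with
lambda = (n-1)*27/N * T, and P(X >= 4) is far below 0.001 at genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of tag clustering and its Poisson background model.

    genome_length is N (nt) and library_size is T (uniquely mapped tags);
    library_size=None means "use the sum of input counts".
    """

    tag_length: int = 27
    min_tags: int = 4
    genome_length: int = 3_095_693_983      # GRCh37 total assembly length
    library_size: int | None = None
    alpha: float = 0.001

    def __post_init__(self):
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.min_tags < 1:
            raise ValueError("min_tags must be >= 1")
        if self.genome_length <= 0:
            raise ValueError("genome_length (N) must be positive")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size (T) must be positive")


@dataclass
class TagCluster:
    """A strand-specific merged set of overlapping tag bodies.

    ``start``/``end`` are the 1-based inclusive genomic span of the merged
    tag bodies; ``positions``/``counts`` hold the 5'-end (CTSS) payload,
    sorted by position.
    """

    chrom: str
    strand: str
    start: int
    end: int
    positions: np.ndarray
    counts: np.ndarray
    rpm: float = np.nan
    p_value: float = np.nan

    def __post_init__(self):
        order = np.argsort(self.positions, kind="stable")
        self.positions = np.asarray(self.positions, dtype=np.int64)[order]
        self.counts = np.asarray(self.counts, dtype=np.int64)[order]
        if len(self.positions) and (
            self.positions[0] < self.start or self.positions[-1] > self.end
        ):
            raise ValueError("CTSS positions outside cluster span")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.start}-{self.end}"

    @property
    def ctss(self) -> dict[int, int]:
        return dict(zip(self.positions.tolist(), self.counts.tolist()))


def tag_body_span(pos: np.ndarray, strand: str, tag_length: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based inclusive genomic span of tag bodies with 5' ends at ``pos``.

    Reads run 5'->3' from the cap, so on the minus strand the body is the
    ``tag_length`` nt ending at the 5'-end position.
    """
    pos = np.asarray(pos, dtype=np.int64)
    if strand == "+":
        return pos, pos + tag_length - 1
    return pos - tag_length + 1, pos


def build_tag_sets(records: pd.DataFrame, params: ClusterParams = ClusterParams()
                   ) -> list[TagCluster]:
    """Single-linkage merge of overlapping same-strand tag bodies.

    Every input tag belongs to exactly one returned set; no count filter is
    applied at this stage.
    """
    out: list[TagCluster] = []
    if records.empty:
        return out
    for (chrom, strand), grp in records.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        cnt = grp["count"].to_numpy(dtype=np.int64)
        keep = cnt > 0
        pos, cnt = pos[keep], cnt[keep]
        if len(pos) == 0:
            continue
        body_s, body_e = tag_body_span(pos, strand, params.tag_length)
        order = np.argsort(body_s, kind="stable")
        pos, cnt, body_s, body_e = pos[order], cnt[order], body_s[order], body_e[order]
        # bodies overlap (>=1 nt, inclusive coords) when next start <= running max end
        running_end = np.maximum.accumulate(body_e)
        breaks = np.flatnonzero(body_s[1:] > running_end[:-1]) + 1
        bounds = np.concatenate([[0], breaks, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            out.append(TagCluster(
                chrom=chrom, strand=strand,
                start=int(body_s[a:b].min()), end=int(body_e[a:b].max()),
                positions=pos[a:b], counts=cnt[a:b],
            ))
    return out


def poisson_pvalue(n: int, params: ClusterParams) -> float:
    """P(X >= n) for X ~ Poisson(lambda), lambda = (n-1)*tag_length/N * T.

    This is the probability that background noise alone produces n tags in
    a tag-set window of (n-1)*tag_length nt.  For n = 1 the window is empty
    (lambda = 0) and the tail probability is 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    T = params.library_size
    if T is None:
        raise ValueError("library_size (T) required for poisson_pvalue")
    lam = (n - 1) * params.tag_length / params.genome_length * T
    if lam == 0.0:
        return 0.0
    return float(stats.poisson.sf(n - 1, lam))


def rpm(count: float, total_mapped: float) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / total_mapped * 1e6


def cluster_tags(records: pd.DataFrame, params: ClusterParams = ClusterParams()
                 ) -> list[TagCluster]:
    """Cluster one sample's CTSS records and keep sets with >= min_tags tags.

    The Poisson rule justifies min_tags globally; every kept cluster's
    background p-value is computed and asserted <= alpha rather than used
    as a per-cluster filter.
    """
    T = params.library_size if params.library_size is not None else int(records["count"].sum())
    if T <= 0:
        raise ValueError("empty library: total tag count must be positive")
    eff = ClusterParams(tag_length=params.tag_length, min_tags=params.min_tags,
                        genome_length=params.genome_length, library_size=T,
                        alpha=params.alpha)
    clusters = [tc for tc in build_tag_sets(records, eff) if tc.n >= eff.min_tags]
    for tc in clusters:
        tc.rpm = rpm(tc.n, T)
        tc.p_value = poisson_pvalue(tc.n, eff)
        if not tc.p_value <= eff.alpha:
            raise AssertionError(
                f"cluster {tc.id} (n={tc.n}) has background p={tc.p_value:.3g} "
                f"> alpha={eff.alpha}; min_tags={eff.min_tags} does not bound "
                f"significance for N={eff.genome_length}, T={T}"
            )
    return clusters


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """Summary table (one row per TC) used by downstream stages."""
    rows = [(tc.id, tc.chrom, tc.strand, tc.start, tc.end, tc.n, tc.rpm, tc.p_value)
            for tc in clusters]
    return pd.DataFrame(rows, columns=["tc_id", "chrom", "strand", "start",
                                       "end", "n", "rpm", "p_value"])
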