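"""Promoter shape classification (SP/DP/MP/BP) and 5'-end distribution
disparity between conditions.

Shape classes describe the 5'-end distribution inside a tag cluster:

* SP - single dominant peak (sharp initiation),
* DP - broad but with one dominant peak,
* MP - broad with well-separated bi/multi peaks,
* BP - generally broad.

The criteria are evaluated strictly in order on clusters with at least 100
tags; percentiles are taken on the tag-weighted position multiset by the
nearest-rank method, and a "peak" is the tag count at a single genomic
position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import TagCluster
from .differential import bh_adjust

SHAPE_CLASSES = ("SP", "DP", "MP", "BP")


@dataclass
class ShapeResult:
    tc_id: str
    shape: str | None            # None when below the tag threshold
    q25: int
    q75: int
    q15: int
    q85: int
    peak1: int
    peak2: int


def weighted_percentile(positions: np.ndarray, counts: np.ndarray, q: float) -> int:
    """Nearest-rank percentile of the tag-weighted position multiset."""
    order = np.argsort(positions, kind="stable")
    positions, counts = positions[order], counts[order]
    n = counts.sum()
    rank = max(1, math.ceil(q / 100.0 * n))
    cum = np.cumsum(counts)
    return int(positions[np.searchsorted(cum, rank)])


def classify_shape(cluster: TagCluster, min_tags: int = 100) -> ShapeResult:
    """Classify one cluster; criteria first-match-wins in the order
    SP (i), DP (ii), MP (iii), else BP (iv).

    (i)   q75-q25 < 4 nt, or q85-q15 < 6 nt;
    (ii)  highest/second-highest peak ratio > 2 and highest peak > 20% of tags;
    (iii) >=2 peaks each > 15% of tags and every consecutive pair (sorted by
          coordinate) more than 5 nt apart;
    (iv)  everything else.
    """
    pos, cnt = cluster.positions, cluster.counts
    n = int(cnt.sum())
    q25 = weighted_percentile(pos, cnt, 25)
    q75 = weighted_percentile(pos, cnt, 75)
    q15 = weighted_percentile(pos, cnt, 15)
    q85 = weighted_percentile(pos, cnt, 85)
    top = np.sort(cnt)[::-1]
    peak1 = int(top[0])
    peak2 = int(top[1]) if len(top) > 1 else 0
    result = ShapeResult(cluster.id, None, q25, q75, q15, q85, peak1, peak2)
    if n < min_tags:
        return result

    if (q75 - q25) < 4 or (q85 - q15) < 6:
        result.shape = "SP"
    elif peak1 > 2 * peak2 and peak1 > 0.2 * n:
        result.shape = "DP"
    else:
        peaks = np.sort(pos[cnt > 0.15 * n])
        if len(peaks) >= 2 and np.all(np.diff(peaks) > 5):
            result.shape = "MP"
        else:
            result.shape = "BP"
    return result


def shapes_to_frame(results: list[ShapeResult]) -> pd.DataFrame:
    rows = [(r.tc_id, r.shape if r.shape else "", r.q25, r.q75, r.q15, r.q85,
             r.peak1, r.peak2) for r in results]
    return pd.DataFrame(rows, columns=["tc_id", "shape", "q25", "q75", "q15",
                                       "q85", "peak1", "peak2"])


# ---------------------------------------------------------------------------
# Cluster matching between conditions


@dataclass
class MatchedPairs:
    pairs: list[tuple[TagCluster, TagCluster]]
    only_a: list[TagCluster]
    only_b: list[TagCluster]


def shared_mass(a: TagCluster, b: TagCluster) -> int:
    """Tag mass on positions used by both clusters: sum of min counts."""
    common, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    if len(common) == 0:
        return 0
    return int(np.minimum(a.counts[ia], b.counts[ib]).sum())


def match_clusters(tcs_a: list[TagCluster], tcs_b: list[TagCluster]) -> MatchedPairs:
    """Pair same-strand clusters whose spans overlap by >= 1 nt.

    Many-to-many overlaps are resolved greedily to the pairs with maximal
    shared-position tag mass (ties broken by overlap length, then ids, for
    determinism); each cluster joins at most one pair.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for j, tc in enumerate(tcs_b):
        by_key.setdefault((tc.chrom, tc.strand), []).append(j)

    candidates = []
    for i, a in enumerate(tcs_a):
        for j in by_key.get((a.chrom, a.strand), []):
            b = tcs_b[j]
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov >= 1:
                candidates.append((-shared_mass(a, b), -ov, a.id, b.id, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((tcs_a[i], tcs_b[j]))
    only_a = [tc for i, tc in enumerate(tcs_a) if i not in used_a]
    only_b = [tc for j, tc in enumerate(tcs_b) if j not in used_b]
    return MatchedPairs(pairs, only_a, only_b)


# ---------------------------------------------------------------------------
# KS disparity


@dataclass
class DisparityResult:
    id_a: str
    id_b: str
    ks_D: float
    p: float
    q: float
    shape_a: str | None
    shape_b: str | None
    changed: bool


def ks_statistic(a: TagCluster, b: TagCluster, n_permutations: int = 0,
                 rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Two-sample KS on the tag-position multisets (each tag one sample
    point).  p is asymptotic by default; with n_permutations > 0 a
    permutation p-value is computed instead (for small clusters)."""
    xa = np.repeat(a.positions, a.counts)
    xb = np.repeat(b.positions, b.counts)
    res = stats.ks_2samp(xa, xb, method="asymp")
    d, p = float(res.statistic), float(res.pvalue)
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        pooled = np.concatenate([xa, xb])
        na = len(xa)
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            dd = stats.ks_2samp(pooled[:na], pooled[na:], method="asymp").statistic
            if dd >= d:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return d, p


def ks_disparity(pairs: list[tuple[TagCluster, TagCluster]], min_tags: int = 100,
                 alpha: float = 0.001,
                 shapes_a: dict[str, str] | None = None,
                 shapes_b: dict[str, str] | None = None) -> list[DisparityResult]:
    """KS disparity over all matched pairs with >= min_tags tags on both
    sides.  Raw p decides ``changed`` (p < alpha); BH-adjusted q is
    reported alongside."""
    tested = [(a, b) for a, b in pairs if a.n >= min_tags and b.n >= min_tags]
    if not tested:
        return []
    stats_p = [ks_statistic(a, b) for a, b in tested]
    qs = bh_adjust(np.array([p for _, p in stats_p]))
    out = []
    for (a, b), (d, p), q in zip(tested, stats_p, qs):
        out.append(DisparityResult(
            a.id, b.id, d, p, float(q),
            (shapes_a or {}).get(a.id), (shapes_b or {}).get(b.id),
            changed=bool(p < alpha)))
    return out


def disparity_to_frame(results: list[DisparityResult]) -> pd.DataFrame:
    rows = [(r.id_a, r.id_b, r.ks_D, r.p, r.q, r.shape_a or "", r.shape_b or "",
             r.changed) for r in results]
    return pd.DataFrame(rows, columns=["tc_translatome", "tc_transcriptome",
                                       "ks_D", "p_value", "q_value",
                                       "shape_translatome", "shape_transcriptome",
                                       "changed"])


# ---------------------------------------------------------------------------
# Shape share vs fold-change trend


def shape_fc_trend(shapes: dict[str, str], fold_changes: dict[str, float],
                   thresholds: list[float]) -> pd.DataFrame:
    """For each minimal-FC cutoff, the fraction of qualifying TCs in the SP
    and in the BP class, plus the Pearson correlation of each fraction
    against the cutoff (NaN when undefined).

    ``fold_changes`` should already be restricted to the TC set of interest
    (e.g. translatome-enriched TCs).
    """
    rows = []
    for th in thresholds:
        ids = [t for t, fc in fold_changes.items() if fc >= th and t in shapes]
        total = len(ids)
        if total == 0:
            rows.append((th, 0, np.nan, np.nan))
            continue
        sp = sum(1 for t in ids if shapes[t] == "SP") / total * 100
        bp = sum(1 for t in ids if shapes[t] == "BP") / total * 100
        rows.append((th, total, sp, bp))
    df = pd.DataFrame(rows, columns=["min_fc", "n_tc", "pct_sp", "pct_bp"])

    def _corr(col: str) -> float:
        sub = df.dropna(subset=[col])
        if len(sub) < 2 or sub[col].nunique() == 1 or sub["min_fc"].nunique() == 1:
            return np.nan
        return float(stats.pearsonr(sub["min_fc"], sub[col])[0])

    df.attrs["pearson_r_sp"] = _corr("pct_sp")
    df.attrs["pearson_r_bp"] = _corr("pct_bp")
    return df
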