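"""Polysome-selection statistics: per-TC abundance change and per-gene
scores.

For a matched TC pair with raw counts (k1, k2) in libraries of sizes
(T1, T2), fold change is the RPM ratio FC = (k1/T1)/(k2/T2) and the
two-sided p-value comes from an exact binomial test of k1 against
k1 + k2 with success probability T1/(T1+T2) (the standard two-library
test for designs without replicates).

Gene level: with per-promoter abundances p_i (translatome) and t_i
(transcriptome),

    E_p = sum_i p_i,  E_t = sum_i t_i,  S_fc = E_p / E_t,
    S_du = 1/2 * sum_i | p_i/E_p - t_i/E_t |.

S_du is half the L1 distance between a gene's promoter-usage proportion
vectors in the two samples: 0 when the gene uses a single promoter or the
same proportions in both samples, 1 when the supported promoter sets are
disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= p, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# TC-level differential abundance


@dataclass
class TcDiff:
    pair_id: str
    k_translatome: int
    k_transcriptome: int
    rpm_translatome: float
    rpm_transcriptome: float
    fc: float                    # NaN when one side is zero
    log2fc: float
    p: float
    q: float = np.nan
    status: str = "unchanged"


def tc_diff(counts: tuple[int, int], totals: tuple[int, int],
            pair_id: str = "", log2fc_threshold: float = 1.0,
            alpha: float = 0.05) -> TcDiff:
    """Exact two-library binomial test for one matched TC pair.

    Pairs with a zero on exactly one side get status translatome_only /
    transcriptome_only with FC undefined; both-zero pairs are invalid.
    """
    k1, k2 = counts
    T1, T2 = totals
    if T1 <= 0 or T2 <= 0:
        raise ValueError("library totals must be positive")
    if k1 + k2 < 1:
        raise ValueError("pair with zero counts on both sides is excluded")
    rpm1 = k1 / T1 * 1e6
    rpm2 = k2 / T2 * 1e6
    p = float(stats.binomtest(k1, k1 + k2, T1 / (T1 + T2)).pvalue)
    if k2 == 0:
        return TcDiff(pair_id, k1, k2, rpm1, rpm2, np.nan, np.nan, p,
                      status="translatome_only")
    if k1 == 0:
        return TcDiff(pair_id, k1, k2, rpm1, rpm2, np.nan, np.nan, p,
                      status="transcriptome_only")
    fc = rpm1 / rpm2
    log2fc = float(np.log2(fc))
    status = "unchanged"
    if log2fc >= log2fc_threshold and p < alpha:
        status = "enriched"
    elif log2fc <= -log2fc_threshold and p < alpha:
        status = "depleted"
    return TcDiff(pair_id, k1, k2, rpm1, rpm2, fc, log2fc, p, status=status)


def tc_diff_table(pairs: list[tuple[str, int, int]], totals: tuple[int, int],
                  log2fc_threshold: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """tc_diff over (pair_id, k1, k2) triples with BH adjustment across
    all tested pairs."""
    results = [tc_diff((k1, k2), totals, pair_id, log2fc_threshold, alpha)
               for pair_id, k1, k2 in pairs]
    qs = bh_adjust([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return pd.DataFrame(
        [(r.pair_id, r.k_translatome, r.k_transcriptome, r.rpm_translatome,
          r.rpm_transcriptome, r.fc, r.log2fc, r.p, r.q, r.status)
         for r in results],
        columns=["pair_id", "k_translatome", "k_transcriptome",
                 "rpm_translatome", "rpm_transcriptome", "fc", "log2fc",
                 "p_value", "q_value", "status"])


# ---------------------------------------------------------------------------
# Gene-level scores


def s_du(p_vec, t_vec) -> float:
    """Differential promoter-usage score: half the L1 distance between the
    two usage proportion vectors.

    Defined when E_p > 0 and E_t > 0 (NaN otherwise); identically 0 for a
    single-promoter gene.  Reported tables restrict to genes with >= 2
    promoters, where the score is informative.
    """
    p_vec = np.asarray(p_vec, dtype=float)
    t_vec = np.asarray(t_vec, dtype=float)
    if p_vec.shape != t_vec.shape:
        raise ValueError("promoter vectors must have equal length")
    ep, et = p_vec.sum(), t_vec.sum()
    if ep <= 0 or et <= 0:
        return np.nan
    return float(0.5 * np.abs(p_vec / ep - t_vec / et).sum())


@dataclass
class GeneScore:
    gene: str
    n_promoters: int
    promoters: list[tuple[float, float]]     # (p_i, t_i) in RPM
    k_translatome: int
    k_transcriptome: int
    E_p: float
    E_t: float
    S_fc: float
    log2_S_fc: float
    p: float
    q: float
    S_du: float
    significant: bool


def gene_scores(gene_promoters: dict[str, list[tuple[float, float, int, int]]],
                totals: tuple[int, int], log2fc_threshold: float = 1.0,
                alpha: float = 0.05) -> list[GeneScore]:
    """Per-gene E_p, E_t, S_fc, S_du.

    ``gene_promoters`` maps gene -> list of (p_rpm, t_rpm, k1, k2) per core
    promoter; unmatched single-sample TCs enter with 0 on the absent side.
    The reported S_fc uses RPM; its significance uses the exact binomial
    test on the summed raw counts, BH-adjusted across genes.
    """
    T1, T2 = totals
    genes = sorted(gene_promoters)
    raw: list[GeneScore] = []
    pvals = []
    for gene in genes:
        promoters = gene_promoters[gene]
        p_vec = np.array([x[0] for x in promoters], dtype=float)
        t_vec = np.array([x[1] for x in promoters], dtype=float)
        k1 = int(sum(x[2] for x in promoters))
        k2 = int(sum(x[3] for x in promoters))
        ep, et = float(p_vec.sum()), float(t_vec.sum())
        if k1 + k2 < 1:
            continue
        p = float(stats.binomtest(k1, k1 + k2, T1 / (T1 + T2)).pvalue)
        sfc = ep / et if et > 0 else np.nan
        du = s_du(p_vec, t_vec)
        raw.append(GeneScore(gene, len(promoters),
                             [(float(a), float(b)) for a, b, _, _ in promoters],
                             k1, k2, ep, et, sfc,
                             float(np.log2(sfc)) if sfc and sfc > 0 else np.nan,
                             p, np.nan, du, False))
        pvals.append(p)
    for score, q in zip(raw, bh_adjust(pvals) if pvals else []):
        score.q = float(q)
        score.significant = bool(np.isfinite(score.log2_S_fc)
                                 and abs(score.log2_S_fc) >= log2fc_threshold
                                 and score.p < alpha)
    return raw


def gene_scores_to_frame(scores: list[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene, s.n_promoters, s.k_translatome, s.k_transcriptome,
          s.E_p, s.E_t, s.S_fc, s.log2_S_fc, s.p, s.q, s.S_du, s.significant)
         for s in scores],
        columns=["gene", "n_promoters", "k_translatome", "k_transcriptome",
                 "E_p", "E_t", "S_fc", "log2_S_fc", "p_value", "q_value",
                 "S_du", "significant"])


# ---------------------------------------------------------------------------
# RPM-matched gene groups


def select_matched_groups(scores: pd.DataFrame, group_size: int = 100
                          ) -> dict[str, pd.DataFrame]:
    """Three disjoint gene groups with similar transcriptome abundance:

    * enriched: top ``group_size`` significant translatome-enriched genes
      (S_fc > 2), ranked by p-value;
    * unchanged: top ``group_size`` genes with 0.9 < S_fc < 1.1, ranked by
      transcriptome RPM (descending);
    * depleted: significant translatome-depleted genes (S_fc < 0.5) ranked
      by p-value, taking ranks group_size+1 .. 2*group_size.
    """
    df = scores
    enriched = (df[(df["S_fc"] > 2) & df["significant"]]
                .sort_values(["p_value", "gene"], kind="mergesort")
                .head(group_size))
    unchanged = (df[(df["S_fc"] > 0.9) & (df["S_fc"] < 1.1)]
                 .sort_values(["E_t", "gene"], ascending=[False, True],
                              kind="mergesort")
                 .head(group_size))
    depleted_all = (df[(df["S_fc"] < 0.5) & df["significant"]]
                    .sort_values(["p_value", "gene"], kind="mergesort"))
    depleted = depleted_all.iloc[group_size:2 * group_size]
    groups = {"enriched": enriched, "unchanged": unchanged, "depleted": depleted}
    for label, grp in groups.items():
        if len(grp) < group_size:
            warnings.warn(f"group {label!r} has only {len(grp)} of "
                          f"{group_size} requested genes")
    return groups


# ---------------------------------------------------------------------------
# Gene-family enrichment


def enrichment_test(query: set[str], families: dict[str, set[str]],
                    universe: set[str]) -> pd.DataFrame:
    """Per-family 2x2 Fisher exact test of a query gene set against a
    universe, BH-adjusted across families.

    ``families`` maps family name -> member gene set.  Odds ratio is inf
    when the off-diagonal is empty (scipy's convention).
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    query = set(query) & universe
    rows = []
    for name in sorted(families):
        members = families[name] & universe
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), len(query), float(odds), float(p)))
    df = pd.DataFrame(rows, columns=["family", "overlap", "family_size",
                                     "query_size", "odds_ratio", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df
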