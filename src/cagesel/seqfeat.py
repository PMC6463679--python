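"""Sequence-window characterization of TC groups: GC content, AUG (start
codon) counts and TATA-box enrichment in the 100 nt around representative
TSSs.

Windows are taken in transcript orientation: the downstream window starts
at the representative TSS itself (position 1) and runs 100 nt 3'-ward; the
upstream window is the 100 nt immediately 5' of it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_cage import Genome

BASES = "ACGT"
TATA_PATTERN = "TATA[AT]A[AT]"       # TATAWAW consensus


@dataclass
class WindowSet:
    """A labelled group of fixed-length sequence windows.

    Windows truncated by contig edges are excluded and counted in
    ``n_excluded``.
    """

    label: str
    sequences: list[str] = field(default_factory=list)
    n_excluded: int = 0
    width: int = 100

    def __post_init__(self):
        bad = [s for s in self.sequences if len(s) != self.width]
        if bad:
            raise ValueError(f"window of length {len(bad[0])} != {self.width}")

    def __len__(self) -> int:
        return len(self.sequences)


def extract_windows(label: str, sites: list[tuple[str, int, str]], genome: Genome,
                    side: str = "downstream", width: int = 100) -> WindowSet:
    """Fetch strand-aware windows around (chrom, rep_tss, strand) sites.

    downstream: rep_tss .. rep_tss+width-1 in transcript orientation
    (position 1 is the representative TSS); upstream: the width nt
    immediately 5' of the representative TSS.
    """
    ws = WindowSet(label, width=width)
    for chrom, rep, strand in sites:
        sign = 1 if strand == "+" else -1
        if side == "downstream":
            lo, hi = rep, rep + sign * (width - 1)
        elif side == "upstream":
            lo, hi = rep - sign * width, rep - sign
        else:
            raise ValueError(f"side must be downstream/upstream, got {side!r}")
        start1, end1 = min(lo, hi), max(lo, hi)
        if start1 < 1 or end1 > genome.length(chrom):
            ws.n_excluded += 1
            continue
        ws.sequences.append(genome.fetch(chrom, start1, end1, strand))
    return ws


def pick_groups(tcdiff: pd.DataFrame, k: int = 200, seed: int = 0,
                fc_band: tuple[float, float] = (0.95, 1.05)) -> dict[str, pd.DataFrame]:
    """Select the three comparison groups from a TC differential table:
    top-k enriched and top-k depleted by p-value, and k TCs picked
    uniformly at random (fixed seed) from the FC band (exclusive bounds).
    """
    enriched = (tcdiff[tcdiff["status"] == "enriched"]
                .sort_values(["p_value", "pair_id"], kind="mergesort").head(k))
    depleted = (tcdiff[tcdiff["status"] == "depleted"]
                .sort_values(["p_value", "pair_id"], kind="mergesort").head(k))
    band = tcdiff[(tcdiff["fc"] > fc_band[0]) & (tcdiff["fc"] < fc_band[1])]
    band = band[~band["pair_id"].isin(enriched["pair_id"])
                & ~band["pair_id"].isin(depleted["pair_id"])]
    band = band.sort_values("pair_id", kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    if len(band) <= k:
        if len(band) < k:
            import warnings
            warnings.warn(f"FC band holds only {len(band)} TCs (< {k}); using all")
        control = band
    else:
        control = band.iloc[np.sort(rng.choice(len(band), size=k, replace=False))]
    return {"enriched": enriched, "depleted": depleted, "control": control}


def gc_profile(ws: WindowSet) -> tuple[float, pd.DataFrame]:
    """Overall GC fraction and per-position base frequencies of a group.

    Non-ACGT bases are tallied per position under 'other' and excluded
    from the frequency denominator.
    """
    if not ws.sequences:
        raise ValueError(f"window set {ws.label!r} is empty")
    arr = np.frombuffer("".join(ws.sequences).encode(), dtype="S1").reshape(
        len(ws.sequences), ws.width)
    counts = {b: (arr == b.encode()).sum(axis=0) for b in BASES}
    other = len(ws.sequences) - sum(counts[b] for b in BASES)
    denom = np.maximum(sum(counts[b] for b in BASES), 1)
    freqs = pd.DataFrame({b: counts[b] / denom for b in BASES})
    freqs["other_count"] = other
    freqs.index = pd.RangeIndex(1, ws.width + 1, name="position")
    gc_total = int(counts["G"].sum() + counts["C"].sum())
    acgt_total = int(sum(counts[b].sum() for b in BASES))
    return gc_total / acgt_total, freqs


def count_aug(ws: WindowSet) -> tuple[int, list[int]]:
    """Total ATG occurrences in the group's (DNA) windows, overlap-aware,
    plus per-window counts."""
    per = [sum(1 for i in range(len(s) - 2) if s[i:i + 3] == "ATG")
           for s in ws.sequences]
    return sum(per), per


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for two proportions k1/n1 vs k2/n2."""
    return float(stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1])


def count_pattern(ws: WindowSet, pattern: str) -> tuple[int, int]:
    """(total overlap-aware matches, windows with >= 1 match)."""
    rx = re.compile(f"(?=({pattern}))")
    per = [len(rx.findall(s)) for s in ws.sequences]
    return sum(per), sum(1 for c in per if c > 0)


def tata_enrichment(ws_a: WindowSet, ws_b: WindowSet,
                    pattern: str = TATA_PATTERN) -> dict:
    """Fold enrichment of TATA-box matches in group a over group b
    (rates of windows containing a match), with a Fisher exact p.

    Fold is inf when group b has no matching window.
    """
    if not ws_a.sequences or not ws_b.sequences:
        raise ValueError("both window sets must be nonempty")
    tot_a, hit_a = count_pattern(ws_a, pattern)
    tot_b, hit_b = count_pattern(ws_b, pattern)
    rate_a = hit_a / len(ws_a)
    rate_b = hit_b / len(ws_b)
    fold = np.inf if rate_b == 0 else rate_a / rate_b
    p = proportion_test(hit_a, len(ws_a), hit_b, len(ws_b))
    return {"matches_a": tot_a, "matches_b": tot_b,
            "windows_with_match_a": hit_a, "windows_with_match_b": hit_b,
            "rate_a": rate_a, "rate_b": rate_b, "fold": float(fold), "p_value": p}


def group_stats(groups: dict[str, WindowSet], upstream: dict[str, WindowSet]
                ) -> pd.DataFrame:
    """Summary table of GC / AUG / TATA statistics per group."""
    rows = []
    for label in groups:
        gc, _ = gc_profile(groups[label])
        aug_total, _ = count_aug(groups[label])
        tata_total, tata_hits = count_pattern(upstream[label], TATA_PATTERN)
        rows.append((label, len(groups[label]), gc, aug_total,
                     tata_total, tata_hits))
    return pd.DataFrame(rows, columns=["group", "n_windows", "gc_fraction",
                                       "aug_total", "tata_matches",
                                       "tata_windows"])


def write_group_fasta(ws: WindowSet, path) -> None:
    """Export a group's windows for external motif tools (e.g. MEME)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(ws.sequences, start=1):
            fh.write(f">{ws.label}_{i}\n{seq}\n")
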