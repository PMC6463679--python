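"""Feature assignment, representative TSSs, 5'UTR lengths, first-nucleotide
frequencies and the optional G-addition correction.

Each tag cluster is reduced to a single position, its representative TSS
(the 5' end with the highest tag count), and assigned to a genomic feature
by the priority 5'UTR (incl. 100 nt upstream) > 3'UTR > CDS > intron, with
everything else intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import TagCluster
from .io_cage import FeatureIndex, Genome

FEATURE_PRIORITY = [
    ("5utr", "five_prime_utr_ext"),
    ("3utr", "three_prime_utr"),
    ("cds", "cds"),
    ("intron", "intron"),
]


@dataclass
class AnnotatedCluster:
    cluster: TagCluster
    feature: str                 # {5utr, 3utr, cds, intron, intergenic}
    gene: str | None
    transcript: str | None
    rep_tss: int                 # 1-based
    rep_tss_count: int
    first_nt: str | None = None


def representative_tss(cluster: TagCluster) -> int:
    """Position of the most frequently used TSS within the cluster.

    Ties on the maximal count are broken toward the 5'-most position
    (smallest coordinate on +, largest on -), which favours the longest
    5'UTR.
    """
    best = cluster.counts.max()
    candidates = cluster.positions[cluster.counts == best]
    return int(candidates.min() if cluster.strand == "+" else candidates.max())


def _pick_transcript(index: FeatureIndex, tx_ids: list[str], rep_tss: int) -> str:
    """Among transcripts containing the position, the one whose annotated
    TSS is nearest the representative TSS (ties: lexicographic id)."""
    return min(tx_ids, key=lambda t: (abs(index.transcripts[t].tss - rep_tss), t))


def assign_feature(cluster: TagCluster, index: FeatureIndex) -> AnnotatedCluster:
    """Assign the cluster (via its representative TSS) to the highest-priority
    feature whose strand-matched interval contains it."""
    rep = representative_tss(cluster)
    rep_count = int(cluster.counts[cluster.positions == rep][0])
    for label, kind in FEATURE_PRIORITY:
        tx_ids = index.query(kind, cluster.chrom, cluster.strand, rep)
        if tx_ids:
            tx = _pick_transcript(index, tx_ids, rep)
            return AnnotatedCluster(cluster, label, index.tx2gene[tx], tx, rep, rep_count)
    return AnnotatedCluster(cluster, "intergenic", None, None, rep, rep_count)


def annotate_clusters(clusters: list[TagCluster], index: FeatureIndex,
                      genome: Genome | None = None) -> list[AnnotatedCluster]:
    out = [assign_feature(tc, index) for tc in clusters]
    if genome is not None:
        for ann in out:
            ann.first_nt = genome.base(ann.cluster.chrom, ann.rep_tss, ann.cluster.strand)
    return out


def annotations_to_frame(annotated: list[AnnotatedCluster]) -> pd.DataFrame:
    rows = [(a.cluster.id, a.cluster.chrom, a.cluster.strand, a.cluster.start,
             a.cluster.end, a.cluster.n, a.cluster.rpm, a.feature,
             a.gene if a.gene is not None else "",
             a.transcript if a.transcript is not None else "",
             a.rep_tss, a.rep_tss_count, a.first_nt if a.first_nt else "")
            for a in annotated]
    return pd.DataFrame(rows, columns=[
        "tc_id", "chrom", "strand", "start", "end", "n", "rpm", "feature",
        "gene", "transcript", "rep_tss", "rep_tss_count", "first_nt"])


# ---------------------------------------------------------------------------
# 5'UTR length


def five_prime_utr_length(annotated: AnnotatedCluster, index: FeatureIndex) -> int | None:
    """Strand-aware distance (nt) from the representative TSS to the first
    base of the nearest downstream annotated start codon of the cluster's
    gene.

    Among the gene's coding transcripts whose extended 5'UTR contains the
    representative TSS and whose start codon lies downstream of it, the one
    with the annotated TSS nearest the representative TSS is used.  Returns
    None (flagged undefined) when no such transcript exists.
    """
    if annotated.gene is None:
        return None
    rep = annotated.rep_tss
    chrom, strand = annotated.cluster.chrom, annotated.cluster.strand
    containing = index.query("five_prime_utr_ext", chrom, strand, rep)
    candidates = []
    for tx in containing:
        model = index.transcripts[tx]
        if model.gene_id != annotated.gene:
            continue
        sc = model.start_codon_pos
        if sc is None:
            continue
        dist = sc - rep if strand == "+" else rep - sc
        if dist >= 0:
            candidates.append((abs(model.tss - rep), tx, dist))
    if not candidates:
        return None
    return min(candidates)[2]


def utr_length_difference(a_translatome: AnnotatedCluster,
                          a_transcriptome: AnnotatedCluster,
                          index: FeatureIndex) -> tuple[int | None, str]:
    """Length difference (translatome - transcriptome) of the 5'UTR defined
    by each sample's representative TSS, with a status in
    {same, shorter, longer, undefined}."""
    lp = five_prime_utr_length(a_translatome, index)
    lt = five_prime_utr_length(a_transcriptome, index)
    if lp is None or lt is None:
        return None, "undefined"
    diff = lp - lt
    status = "same" if diff == 0 else ("shorter" if diff < 0 else "longer")
    return diff, status


# ---------------------------------------------------------------------------
# First-nucleotide frequencies


def first_nt_frequency(annotated: list[AnnotatedCluster], genome: Genome) -> pd.Series:
    """Frequencies of the (strand-aware) base at representative TSSs.

    Frequencies are over {A,C,G,T} and sum to 1; non-ACGT bases are tallied
    under 'other' and excluded from the denominator.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "other": 0}
    for ann in annotated:
        base = ann.first_nt or genome.base(ann.cluster.chrom, ann.rep_tss,
                                           ann.cluster.strand)
        counts[base if base in "ACGT" else "other"] += 1
    total = sum(counts[b] for b in "ACGT")
    freqs = {b: (counts[b] / total if total else np.nan) for b in "ACGT"}
    freqs["other_count"] = counts["other"]
    return pd.Series(freqs)


# ---------------------------------------------------------------------------
# G-addition correction (optional stage)


def g_correction(records: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Single-base correction of the CAGE G-addition bias.

    Reverse transcription adds a non-templated G to many CAGE reads.  A tag
    whose sequenced first base (the ``first_nt`` column) is G but whose
    genomic base at its mapped 5' end is not G is moved 1 nt 3'-ward
    (pos+1 on +, pos-1 on -) and counts are re-aggregated.  Total tag count
    is conserved.
    """
    if "first_nt" not in records.columns:
        raise ValueError(
            "g_correction requires a 'first_nt' column (sequenced first base "
            "per CTSS row); 4-column CTSS tables carry no read sequence"
        )
    df = records.copy()
    genome_base = [genome.base(r.chrom, r.pos, r.strand) for r in df.itertuples(index=False)]
    shift = (df["first_nt"].to_numpy() == "G") & (np.array(genome_base) != "G")
    step = np.where(df["strand"].to_numpy() == "+", 1, -1)
    df["pos"] = df["pos"].to_numpy() + np.where(shift, step, 0)
    out = (df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
             .sort_values(["chrom", "strand", "pos"], kind="mergesort")
             .reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# Expressed transcripts / genes


def expressed_flags(annotated: list[AnnotatedCluster], index: FeatureIndex
                    ) -> tuple[dict[str, bool], dict[str, bool]]:
    """Per-transcript and per-gene expressed flags from one sample's TCs.

    A transcript is expressed iff at least one TC's representative TSS lies
    in its extended 5'UTR; a gene iff at least one of its transcripts is.
    Gene-level calls follow the transcriptome by definition, so pass the
    transcriptome's annotated clusters when gene flags are wanted.
    """
    tx_flags = {tx: False for tx in index.transcripts}
    for ann in annotated:
        for tx in index.query("five_prime_utr_ext", ann.cluster.chrom,
                              ann.cluster.strand, ann.rep_tss):
            tx_flags[tx] = True
    gene_flags = {gene: any(tx_flags[t] for t in txs)
                  for gene, txs in index.gene2tx.items()}
    return tx_flags, gene_flags
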