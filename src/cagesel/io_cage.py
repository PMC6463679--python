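"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
CTSS tables and all emitted tables use 1-based genomic positions, matching
the CAGEr/FANTOM CTSS dialect.  All *internal* interval arithmetic
(FeatureIndex, tag bodies) is 0-based half-open; the conversion is
``pos0 = pos1 - 1`` and is lossless in both directions.

A CTSS table is tab-separated with four columns::

    chrom    pos(1-based 5'-end)    strand(+/-)    count

An optional fifth column ``first_nt`` (the sequenced first base of the tags
at that position) is accepted and carried through; it is only needed by the
optional G-addition correction stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree
from pyfaidx import Fasta

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CtssParseError(ValueError):
    """Malformed CTSS input; carries the offending 1-based line number."""


def validate_ctss(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the CTSS invariants and return the table sorted by
    (chrom, strand, pos).

    Invariants: pos >= 1, count >= 0, strand in {+,-}, and
    (chrom, pos, strand) unique.
    """
    if not set(CTSS_COLUMNS) <= set(df.columns):
        raise CtssParseError(f"CTSS table must have columns {CTSS_COLUMNS}")
    if (df["pos"] < 1).any():
        raise CtssParseError("CTSS positions must be >= 1 (1-based)")
    if (df["count"] < 0).any():
        raise CtssParseError("negative tag count")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise CtssParseError(f"invalid strand value {df['strand'][bad].iloc[0]!r}")
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos", "strand"], keep=False)]
        key = dup.iloc[0]
        raise CtssParseError(
            f"duplicate CTSS key ({key['chrom']}, {key['pos']}, {key['strand']})"
        )
    return df.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def read_ctss(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CTSS TSV into a validated, sorted DataFrame.

    Lines starting with ``#`` are comments.  A malformed line raises
    :class:`CtssParseError` naming its line number.
    """
    rows: list[tuple] = []
    has_nt = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise CtssParseError(f"line {lineno}: expected 4 or 5 columns, got {len(parts)}")
            if has_nt is None:
                has_nt = len(parts) == 5
            elif has_nt != (len(parts) == 5):
                raise CtssParseError(f"line {lineno}: inconsistent column count")
            chrom, pos_s, strand, count_s = parts[:4]
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise CtssParseError(f"line {lineno}: {exc}") from None
            rows.append((chrom, pos, strand, count) + ((parts[4],) if has_nt else ()))
    cols = CTSS_COLUMNS + (["first_nt"] if has_nt else [])
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=("int64" if c in ("pos", "count") else "object"))
                           for c in CTSS_COLUMNS})
    return validate_ctss(df)


def write_ctss(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in CTSS_COLUMNS + ["first_nt"] if c in df.columns]
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one annotated transcript (0-based half-open)."""

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]           # sorted by start
    cds: list[tuple[int, int]]             # sorted by start; empty if non-coding

    @property
    def tss(self) -> int:
        """Annotated TSS, 1-based."""
        if self.strand == "+":
            return self.exons[0][0] + 1
        return self.exons[-1][1]

    @property
    def start_codon_pos(self) -> int | None:
        """1-based genomic position of the first base of the start codon."""
        if not self.cds:
            return None
        if self.strand == "+":
            return self.cds[0][0] + 1
        return self.cds[-1][1]


@dataclass
class FeatureIndex:
    """Strand-aware interval index over annotated genomic features.

    ``trees`` maps (kind, chrom, strand) -> IntervalTree of 0-based half-open
    intervals whose data is the transcript id.  Feature kinds are
    ``five_prime_utr_ext`` (5'UTR plus 100 nt upstream), ``three_prime_utr``,
    ``cds`` and ``intron``.
    """

    trees: dict[tuple[str, str, str], IntervalTree] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    tx2gene: dict[str, str] = field(default_factory=dict)
    gene2tx: dict[str, list[str]] = field(default_factory=dict)
    utr5_extension: int = 100

    FEATURE_KINDS = ("five_prime_utr_ext", "three_prime_utr", "cds", "intron")

    def _add(self, kind: str, chrom: str, strand: str, start0: int, end0: int, tx: str) -> None:
        if end0 <= start0:
            return
        key = (kind, chrom, strand)
        self.trees.setdefault(key, IntervalTree()).addi(start0, end0, tx)

    def query(self, kind: str, chrom: str, strand: str, pos1: int) -> list[str]:
        """Transcript ids whose *kind* interval contains the 1-based position."""
        tree = self.trees.get((kind, chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos1 - 1))


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def read_annotation(path: str | os.PathLike, utr5_extension: int = 100) -> FeatureIndex:
    """Build a :class:`FeatureIndex` from a GTF/GFF file.

    Only ``exon`` and ``CDS`` features are used.  Introns are the gaps
    between consecutive exons of a transcript; the 5'UTR is the exonic
    sequence 5' of the first CDS base and is extended ``utr5_extension`` nt
    upstream of the annotated TSS; the 3'UTR is the exonic sequence 3' of
    the last CDS base.  Non-coding transcripts contribute introns only.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}: line {lineno}: cannot parse: {exc}") from None
            ftype = feat.featuretype.lower()
            if ftype not in ("exon", "cds"):
                continue
            tx = _attr(feat, "transcript_id", "Parent")
            gene = _attr(feat, "gene_id", "gene")
            if tx is None:
                raise ValueError(f"{path}: line {lineno}: {feat.featuretype} without transcript_id/Parent")
            meta.setdefault(tx, (gene or tx, feat.seqid, feat.strand))
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            (exons if ftype == "exon" else cds).setdefault(tx, []).append(iv)

    index = FeatureIndex(utr5_extension=utr5_extension)
    for tx in sorted(meta):
        gene, chrom, strand = meta[tx]
        if tx not in exons:
            if tx in cds:
                raise ValueError(f"transcript {tx} has CDS but no exons")
            continue
        ex = sorted(exons[tx])
        cd = sorted(cds.get(tx, []))
        model = TranscriptModel(tx, gene, chrom, strand, ex, cd)
        index.transcripts[tx] = model
        index.tx2gene[tx] = gene
        index.gene2tx.setdefault(gene, []).append(tx)

        # introns: gaps between consecutive exons
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            index._add("intron", chrom, strand, e1, s2, tx)
        for s, e in cd:
            index._add("cds", chrom, strand, s, e, tx)
        if cd:
            if strand == "+":
                cds_first = cd[0][0]          # 0-based first CDS base
                cds_last_end = cd[-1][1]
                for s, e in ex:
                    index._add("five_prime_utr_ext", chrom, strand, s, min(e, cds_first), tx)
                    index._add("three_prime_utr", chrom, strand, max(s, cds_last_end), e, tx)
                tss0 = ex[0][0]
                index._add("five_prime_utr_ext", chrom, strand,
                           max(0, tss0 - utr5_extension), tss0, tx)
            else:
                cds_first = cd[-1][1]          # exclusive bound of 5'-most CDS base
                cds_last_start = cd[0][0]
                for s, e in ex:
                    index._add("five_prime_utr_ext", chrom, strand, max(s, cds_first), e, tx)
                    index._add("three_prime_utr", chrom, strand, s, min(e, cds_last_start), tx)
                tss0_end = ex[-1][1]
                index._add("five_prime_utr_ext", chrom, strand,
                           tss0_end, tss0_end + utr5_extension, tx)
    return index


# ---------------------------------------------------------------------------
# Genome access


class GenomeError(KeyError):
    pass


class Genome:
    """Thin strand-aware wrapper over a (faidx-indexed) FASTA file."""

    def __init__(self, path: str | os.PathLike):
        self.path = str(path)
        self._fa = Fasta(self.path, as_raw=True, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def length(self, chrom: str) -> int:
        try:
            return len(self._fa[chrom])
        except KeyError:
            raise GenomeError(f"chromosome {chrom!r} not in {self.path}") from None

    @property
    def total_length(self) -> int:
        return sum(len(self._fa[c]) for c in self._fa.keys())

    def fetch(self, chrom: str, start1: int, end1: int, strand: str = "+") -> str:
        """Sequence of [start1, end1] (1-based inclusive) on the given strand.

        On the minus strand the reverse complement is returned, so the
        string always reads 5'->3' in transcript orientation.
        """
        if chrom not in self._fa:
            raise GenomeError(f"chromosome {chrom!r} not in {self.path}")
        if start1 < 1 or end1 > self.length(chrom) or start1 > end1:
            raise GenomeError(f"window {chrom}:{start1}-{end1} out of bounds")
        seq = str(self._fa[chrom][start1 - 1:end1])
        return revcomp(seq) if strand == "-" else seq

    def base(self, chrom: str, pos1: int, strand: str = "+") -> str:
        return self.fetch(chrom, pos1, pos1, strand)


def read_fasta(path: str | os.PathLike) -> Genome:
    return Genome(path)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tag-cluster tables

TC_TABLE_COLUMNS = [
    "tc_id", "chrom", "strand", "start", "end", "n", "rpm", "p_value",
]


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                params: dict | None = None, float_format: str = "%.6g") -> None:
    """Write a TSV with ``#``-prefixed provenance header lines."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# cagesel {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tc_table(clusters: Iterable, path: str | os.PathLike,
                   params: dict | None = None) -> None:
    """Serialize TagClusters (clustering.TagCluster) with their CTSS payload.

    Per-position counts are packed as ``pos:count`` pairs so the round-trip
    is bit-exact on all fields.
    """
    rows = []
    for tc in clusters:
        ctss = ";".join(f"{p}:{c}" for p, c in zip(tc.positions, tc.counts))
        rows.append((tc.id, tc.chrom, tc.strand, tc.start, tc.end, tc.n,
                     repr(tc.rpm), repr(tc.p_value), ctss))
    df = pd.DataFrame(rows, columns=TC_TABLE_COLUMNS + ["ctss"])
    write_table(df, path, params=params)


def read_tc_table(path: str | os.PathLike) -> list:
    from .clustering import TagCluster

    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"rpm": str, "p_value": str})
    out = []
    for row in df.itertuples(index=False):
        pairs = [item.split(":") for item in row.ctss.split(";")]
        positions = np.array([int(p) for p, _ in pairs], dtype=np.int64)
        counts = np.array([int(c) for _, c in pairs], dtype=np.int64)
        out.append(TagCluster(chrom=row.chrom, strand=row.strand,
                              start=int(row.start), end=int(row.end),
                              positions=positions, counts=counts,
                              rpm=float(row.rpm), p_value=float(row.p_value)))
    return out
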