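"""Two-condition synthetic CAGE dataset generator with a truth key.

The generator emits a genome FASTA, a GTF annotation and two CTSS tables
(translatome and transcriptome) that emulate the statistical structure the
pipeline assumes: tag clusters of parameterized shape (SP/DP/MP/BP
emitters), per-condition abundance with planted log2 fold changes, a
subset of clusters with shifted 5'-end distributions between conditions,
uniform genomic background noise, and planted sequence context (first
nucleotide, TATA boxes, downstream GC/AUG differences) so every stage of
the analysis is recoverable against the truth key.

What it does NOT emulate: sequencing error, mappability, multi-mapping,
real promoter sequence grammar, or replicate structure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_cage import revcomp, write_fasta


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults are sized so the full two-condition pipeline runs in minutes
    on one CPU: ~2e4 tag clusters and 1e6 tags per condition.
    """

    seed: int = 1
    n_genes: int = 10_000
    promoter_number_probs: tuple[float, ...] = (0.3, 0.4, 0.3)  # P(1..3 promoters)
    shape_mix: tuple[float, float, float, float] = (0.45, 0.25, 0.10, 0.20)  # SP,DP,MP,BP
    library_size: tuple[int, int] = (1_000_000, 1_000_000)      # translatome, transcriptome
    background_rate: float = 0.01          # fraction of each library that is noise
    abundance_sigma: float = 1.2           # log-normal spread of baseline TC abundance
    fc_fraction: float = 0.30              # fraction of TCs (or genes) with planted log2FC
    fc_log2_range: tuple[float, float] = (1.0, 3.0)
    fc_scope: str = "tc"                   # "tc" or "gene" (same multiplier per gene)
    du_fraction: float = 0.20              # genes with redistributed translatome usage
    shift_fraction: float = 0.30           # TCs with a planted 5'-end distribution shift
    shift_range: tuple[int, int] = (5, 10)
    first_nt_probs: tuple[float, float, float, float] = (0.30, 0.20, 0.35, 0.15)  # A,C,G,T
    tata_rate_enriched: float = 0.50
    tata_rate_other: float = 0.08
    gc_by_group: tuple[float, float, float] = (0.35, 0.45, 0.55)  # enriched, neutral, depleted
    extra_aug_enriched: int = 2
    two_exon_fraction: float = 0.30
    n_chroms: int = 2
    min_tags_floor: int = 4       # every truth TC gets >= this in one condition

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(sum(self.shape_mix) - 1) > 1e-9:
            raise ValueError("shape_mix must sum to 1")
        if abs(sum(self.promoter_number_probs) - 1) > 1e-9:
            raise ValueError("promoter_number_probs must sum to 1")
        for name in ("background_rate", "fc_fraction", "du_fraction", "shift_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.library_size) <= 0:
            raise ValueError("library sizes must be positive")
        if abs(sum(self.first_nt_probs) - 1) > 1e-9:
            raise ValueError("first_nt_probs must sum to 1")


@dataclass
class SimBundle:
    """Paths of the emitted files plus the in-memory truth key."""

    fasta: str
    gtf: str
    ctss_translatome: str
    ctss_transcriptome: str
    tc_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    genome_length: int


SHAPES = ("SP", "DP", "MP", "BP")

# gene-locus layout constants (nt)
_UPSTREAM_MARGIN = 200        # room for the 100-nt UTR extension + TATA window
_PROMOTER_SPACING = 600
_CDS_LEN = 300
_UTR3_LEN = 100
_DOWNSTREAM_MARGIN = 100
_GENE_GAP = 300
_EMITTER_HALF = 36            # maximal emitter support around the mode


def _emitter(shape: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (transcript-oriented, mode at 0) and probabilities of one
    TC's 5'-end emitter."""
    if shape == "SP":
        off = np.arange(-2, 3)
        pr = np.array([0.015, 0.06, 0.85, 0.06, 0.015])
    elif shape == "DP":
        off = np.arange(-18, 19)
        broad = np.exp(-0.5 * (off / 8.0) ** 2)
        pr = broad / broad.sum() * 0.65
        pr[off == 0] += 0.35
    elif shape == "MP":
        if rng.random() < 0.5:
            off = np.array([-5, -4, -3, 3, 4, 5])
            pr = np.array([0.05, 0.42, 0.05, 0.05, 0.38, 0.05])
        else:
            off = np.array([-7, -6, -5, -1, 0, 1, 5, 6, 7])
            pr = np.array([0.033, 0.30, 0.033, 0.033, 0.25, 0.034,
                           0.033, 0.25, 0.034])
    elif shape == "BP":
        sd = rng.uniform(8, 12)
        off = np.arange(-_EMITTER_HALF, _EMITTER_HALF + 1)
        pr = np.exp(-0.5 * (off / sd) ** 2)
        pr = pr / pr.sum()
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return off, pr / pr.sum()


def _plant(seq: np.ndarray, pos5: int, strand: str, s: str) -> None:
    """Write string ``s`` into the chromosome array so that it reads
    5'->3' from 1-based position ``pos5`` in transcript orientation."""
    if strand == "+":
        seq[pos5 - 1:pos5 - 1 + len(s)] = np.frombuffer(s.encode(), dtype="S1")
    else:
        rc = revcomp(s)
        seq[pos5 - len(s):pos5] = np.frombuffer(rc.encode(), dtype="S1")


def simulate(config: SimConfig, out_dir: str | os.PathLike) -> SimBundle:
    """Generate the dataset bundle under ``out_dir``.

    Identical configs (including seed) produce byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    out_dir = str(out_dir)

    # ---- gene layout -----------------------------------------------------
    n_promoters = rng.choice(np.arange(1, len(config.promoter_number_probs) + 1),
                             size=config.n_genes, p=config.promoter_number_probs)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    two_exon = rng.random(config.n_genes) < config.two_exon_fraction
    utr5_len = rng.integers(60, 201, size=config.n_genes)

    gene_span = (_UPSTREAM_MARGIN + (n_promoters - 1) * _PROMOTER_SPACING
                 + utr5_len + np.where(two_exon, 300, 0)
                 + _CDS_LEN + _UTR3_LEN + _DOWNSTREAM_MARGIN)
    chrom_of = np.arange(config.n_genes) % config.n_chroms
    chrom_names = [f"chrS{i + 1}" for i in range(config.n_chroms)]
    offsets = np.zeros(config.n_genes, dtype=np.int64)
    chrom_len = np.full(config.n_chroms, _GENE_GAP, dtype=np.int64)
    for g in range(config.n_genes):
        c = chrom_of[g]
        offsets[g] = chrom_len[c]
        chrom_len[c] += gene_span[g] + _GENE_GAP
    genome_length = int(chrom_len.sum())

    # ---- per-TC truth assignments ---------------------------------------
    tc_rows = []        # layout rows; abundance filled later
    for g in range(config.n_genes):
        gene = f"gene{g:05d}"
        chrom = chrom_names[chrom_of[g]]
        strand = strands[g]
        span = int(gene_span[g])
        lo = int(offsets[g])            # 0-based window start
        # transcript-oriented coordinate u in [0, span): u=0 at the gene's
        # 5'-most point; genomic pos1 = lo+1+u (+) or lo+span-u (-)
        def upos(u: int) -> int:
            return lo + 1 + u if strand == "+" else lo + span - u
        for k in range(int(n_promoters[g])):
            u_tss = _UPSTREAM_MARGIN + k * _PROMOTER_SPACING
            tc_rows.append((gene, k, chrom, strand, span, lo, u_tss, upos(u_tss)))

    tc = pd.DataFrame(tc_rows, columns=["gene", "k", "chrom", "strand",
                                        "gene_span", "gene_lo", "u_tss", "tss"])
    n_tc = len(tc)
    tc["tc_key"] = tc["gene"] + "_p" + (tc["k"] + 1).astype(str)
    tc["true_shape"] = rng.choice(SHAPES, size=n_tc, p=config.shape_mix)
    base = rng.lognormal(mean=np.log(30.0), sigma=config.abundance_sigma, size=n_tc)

    # planted abundance effects
    if config.fc_scope == "gene":
        gene_ids, inv = np.unique(tc["gene"], return_inverse=True)
        gene_eff = np.zeros(len(gene_ids))
        hit = rng.random(len(gene_ids)) < config.fc_fraction
        mag = rng.uniform(*config.fc_log2_range, size=len(gene_ids))
        sign = np.where(rng.random(len(gene_ids)) < 0.5, 1.0, -1.0)
        gene_eff[hit] = (mag * sign)[hit]
        planted = gene_eff[inv]
    elif config.fc_scope == "tc":
        planted = np.zeros(n_tc)
        hit = rng.random(n_tc) < config.fc_fraction
        mag = rng.uniform(*config.fc_log2_range, size=n_tc)
        sign = np.where(rng.random(n_tc) < 0.5, 1.0, -1.0)
        planted[hit] = (mag * sign)[hit]
    else:
        raise ValueError("fc_scope must be 'tc' or 'gene'")
    tc["planted_log2fc"] = planted
    w_p = base * np.exp2(planted / 2.0)
    w_t = base * np.exp2(-planted / 2.0)

    # independent usage redistribution: reshuffle a gene's translatome
    # weights with a Dirichlet draw, preserving the gene's total
    gene_codes, gene_inv = np.unique(tc["gene"], return_inverse=True)
    du_genes = rng.random(len(gene_codes)) < config.du_fraction
    for gi in np.flatnonzero(du_genes):
        idx = np.flatnonzero(gene_inv == gi)
        if len(idx) < 2:
            continue
        total = w_p[idx].sum()
        w_p[idx] = total * rng.dirichlet(np.ones(len(idx)))
    tc["w_p"], tc["w_t"] = w_p, w_t
    tc["exp_log2fc"] = np.log2((w_p / w_p.sum()) / (w_t / w_t.sum()))

    # disparity planting: the transcriptome emitter is shifted downstream
    shifted = rng.random(n_tc) < config.shift_fraction
    shift_nt = np.where(shifted,
                        rng.integers(config.shift_range[0],
                                     config.shift_range[1] + 1, size=n_tc), 0)
    tc["shifted"], tc["shift_nt"] = shifted, shift_nt

    grp = np.where(tc["planted_log2fc"] >= 1, "enriched",
                   np.where(tc["planted_log2fc"] <= -1, "depleted", "neutral"))
    tc["group"] = grp
    tc["first_nt"] = rng.choice(list("ACGT"), size=n_tc, p=config.first_nt_probs)
    tata_rate = np.where(grp == "enriched", config.tata_rate_enriched,
                         config.tata_rate_other)
    tc["tata"] = rng.random(n_tc) < tata_rate

    # ---- draw tag counts -------------------------------------------------
    n_bg = [int(round(L * config.background_rate)) for L in config.library_size]
    n_main = [L - b for L, b in zip(config.library_size, n_bg)]
    tags_p = rng.multinomial(n_main[0], w_p / w_p.sum())
    tags_t = rng.multinomial(n_main[1], w_t / w_t.sum())

    # no silently untestable truth entries: a TC below the clustering
    # floor in both conditions is topped up (in its better condition)
    # with tags borrowed from that condition's most abundant TC, so
    # library sizes are preserved
    floor = config.min_tags_floor
    for i in np.flatnonzero((tags_p < floor) & (tags_t < floor)):
        target = tags_p if tags_p[i] >= tags_t[i] else tags_t
        donor = int(np.argmax(target))
        need = floor - target[i]
        target[donor] -= need
        target[i] += need

    emitters = [_emitter(s, rng) for s in tc["true_shape"]]
    sign_arr = np.where(tc["strand"].to_numpy() == "+", 1, -1)
    tss_arr = tc["tss"].to_numpy()

    chrom_arr = tc["chrom"].to_numpy()
    strand_arr = tc["strand"].to_numpy()

    def _draw_condition(tags: np.ndarray, shift_for_cond: np.ndarray
                        ) -> list[pd.DataFrame]:
        pos_l, cnt_l, tci_l = [], [], []
        for i in range(n_tc):
            if tags[i] == 0:
                continue
            off, pr = emitters[i]
            cnt = rng.multinomial(tags[i], pr)
            nz = cnt > 0
            pos_l.append(tss_arr[i] + sign_arr[i] * (off[nz] + shift_for_cond[i]))
            cnt_l.append(cnt[nz])
            tci_l.append(np.full(int(nz.sum()), i))
        if not pos_l:
            return []
        tci = np.concatenate(tci_l)
        return [pd.DataFrame({"chrom": chrom_arr[tci],
                              "pos": np.concatenate(pos_l),
                              "strand": strand_arr[tci],
                              "count": np.concatenate(cnt_l)})]

    zero = np.zeros(n_tc, dtype=int)
    frames_p = _draw_condition(tags_p, zero)
    frames_t = _draw_condition(tags_t, shift_nt.astype(int))

    def _background(n: int) -> pd.DataFrame:
        lens = np.array([chrom_len[c] for c in range(config.n_chroms)], dtype=float)
        ci = rng.choice(config.n_chroms, size=n, p=lens / lens.sum())
        pos = rng.integers(1, chrom_len[ci] + 1)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        return pd.DataFrame({"chrom": np.array(chrom_names)[ci], "pos": pos,
                             "strand": strand, "count": 1})

    def _finalize(frames: list[pd.DataFrame], bg_n: int) -> pd.DataFrame:
        frames = frames + ([_background(bg_n)] if bg_n else [])
        df = pd.concat(frames, ignore_index=True)
        return (df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                  .sum()
                  .sort_values(["chrom", "strand", "pos"], kind="mergesort")
                  .reset_index(drop=True))

    ctss_p = _finalize(frames_p, n_bg[0])
    ctss_t = _finalize(frames_t, n_bg[1])

    # ---- genome sequence with planted context ---------------------------
    gc_map = dict(zip(("enriched", "neutral", "depleted"),
                      config.gc_by_group))
    chrom_seqs: dict[str, np.ndarray] = {}
    for c, name in enumerate(chrom_names):
        n = int(chrom_len[c])
        chrom_seqs[name] = rng.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=n, p=[0.25] * 4)

    for i in range(n_tc):
        seq = chrom_seqs[tc["chrom"].iloc[i]]
        strand = tc["strand"].iloc[i]
        tss = int(tss_arr[i])
        sign = int(sign_arr[i])
        gc = gc_map[tc["group"].iloc[i]]
        win = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=100,
                         p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        _plant(seq, tss if strand == "+" else tss, strand,
               win.tobytes().decode())
        if tc["group"].iloc[i] == "enriched" and config.extra_aug_enriched:
            n_extra = rng.binomial(2 * config.extra_aug_enriched, 0.5)
            for u in sorted(rng.integers(10, 95, size=n_extra).tolist()):
                _plant(seq, tss + sign * u, strand, "ATG")
        if bool(tc["tata"].iloc[i]):
            _plant(seq, tss - sign * 31, strand, "TATAAAA")
        _plant(seq, tss, strand, str(tc["first_nt"].iloc[i]))

    # ---- write files -----------------------------------------------------
    fasta_path = os.path.join(out_dir, "genome.fa")
    write_fasta({name: chrom_seqs[name].tobytes().decode()
                 for name in chrom_names}, fasta_path)

    gtf_path = os.path.join(out_dir, "annotation.gtf")
    _write_gtf(gtf_path, tc, n_promoters, two_exon, utr5_len)

    ctss_p_path = os.path.join(out_dir, "translatome.ctss.tsv")
    ctss_t_path = os.path.join(out_dir, "transcriptome.ctss.tsv")
    ctss_p.to_csv(ctss_p_path, sep="\t", index=False, header=False)
    ctss_t.to_csv(ctss_t_path, sep="\t", index=False, header=False)

    # ---- truth key -------------------------------------------------------
    tc_truth = tc[["tc_key", "gene", "chrom", "strand", "tss", "true_shape",
                   "w_p", "w_t", "planted_log2fc", "exp_log2fc", "shifted",
                   "shift_nt", "group", "first_nt", "tata"]].copy()
    gene_truth = _gene_truth(tc)
    tc_truth.to_csv(os.path.join(out_dir, "truth_tc.tsv"), sep="\t", index=False)
    gene_truth.to_csv(os.path.join(out_dir, "truth_gene.tsv"), sep="\t", index=False)

    return SimBundle(fasta_path, gtf_path, ctss_p_path, ctss_t_path,
                     tc_truth, gene_truth, genome_length)


def _gene_truth(tc: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gene, sub in tc.groupby("gene", sort=True):
        wp = sub["w_p"].to_numpy()
        wt = sub["w_t"].to_numpy()
        sfc = wp.sum() / wt.sum()
        if len(sub) >= 2:
            sdu = 0.5 * np.abs(wp / wp.sum() - wt / wt.sum()).sum()
        else:
            sdu = np.nan
        rows.append((gene, len(sub), sfc, np.log2(sfc), sdu))
    return pd.DataFrame(rows, columns=["gene", "n_promoters", "true_S_fc",
                                       "true_log2_S_fc", "true_S_du"])


def _write_gtf(path: str, tc: pd.DataFrame, n_promoters: np.ndarray,
               two_exon: np.ndarray, utr5_len: np.ndarray) -> None:
    """One transcript per promoter; all transcripts of a gene share the CDS
    placed downstream of the gene's 3'-most promoter.  A fraction of
    single-promoter genes get a two-exon structure (intron inside the
    5'UTR) so intron assignment is exercised."""
    lines = []
    for gene, sub in tc.groupby("gene", sort=True):
        g = int(gene[4:])
        chrom = sub["chrom"].iloc[0]
        strand = sub["strand"].iloc[0]
        span = int(sub["gene_span"].iloc[0])
        lo = int(sub["gene_lo"].iloc[0])
        npro = int(n_promoters[g])
        L5 = int(utr5_len[g])
        split = bool(two_exon[g]) and npro == 1

        def upos(u: int) -> int:
            return lo + 1 + u if strand == "+" else lo + span - u

        u_last = _UPSTREAM_MARGIN + (npro - 1) * _PROMOTER_SPACING
        u_cds0 = u_last + L5 + (300 if split else 0)
        u_cds1 = u_cds0 + _CDS_LEN - 1
        u_end = u_cds1 + _UTR3_LEN

        for k in range(npro):
            tx = f"{gene}.t{k + 1}"
            u_tss = _UPSTREAM_MARGIN + k * _PROMOTER_SPACING
            attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
            if split and k == 0:
                # exon1 = first 100 nt of the 5'UTR, 200-nt intron, exon2
                exon_units = [(u_tss, u_tss + 99), (u_tss + 300, u_end)]
            else:
                exon_units = [(u_tss, u_end)]
            for ua, ub in exon_units:
                a, b = sorted((upos(ua), upos(ub)))
                lines.append((chrom, a, f"{chrom}\tcagesel_sim\texon\t{a}\t{b}\t.\t{strand}\t.\t{attrs}"))
            a, b = sorted((upos(u_cds0), upos(u_cds1)))
            lines.append((chrom, a, f"{chrom}\tcagesel_sim\tCDS\t{a}\t{b}\t.\t{strand}\t0\t{attrs}"))
    lines.sort()
    with open(path, "w") as fh:
        for _, _, line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Truth comparison


def truth_compare(outputs: dict, bundle: SimBundle) -> dict:
    """Recovery report of pipeline outputs against the truth key.

    ``outputs`` may contain (all optional):

    * ``annotated_translatome`` / ``annotated_transcriptome``: annotation
      frames with tc_id/chrom/strand/start/end,
    * ``shapes_transcriptome``: tc_id -> shape frame,
    * ``disparity``: disparity frame,
    * ``tcdiff``: TC differential frame (pair_id = "idA|idB"),
    * ``gene_scores``: gene score frame.

    Detected TCs are matched to truth promoters by containment of the true
    mode position in the detected cluster span (same chrom/strand).
    """
    truth = bundle.tc_truth

    def _locate(frame: pd.DataFrame) -> pd.Series:
        """truth tc_key -> detected tc_id (NaN when unrecovered)."""
        result = pd.Series(index=truth["tc_key"], dtype="object")
        for (chrom, strand), sub in frame.groupby(["chrom", "strand"], sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            ids = sub["tc_id"].to_numpy()
            mask = (truth["chrom"] == chrom) & (truth["strand"] == strand)
            pos = truth.loc[mask, "tss"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
            keys = truth.loc[mask, "tc_key"].to_numpy()
            result[keys[ok]] = ids[idx[ok]]
        return result

    report: dict = {}
    loc_p = loc_t = None
    if "annotated_translatome" in outputs:
        loc_p = _locate(outputs["annotated_translatome"])
        report["recovered_translatome"] = float(loc_p.notna().mean())
    if "annotated_transcriptome" in outputs:
        loc_t = _locate(outputs["annotated_transcriptome"])
        report["recovered_transcriptome"] = float(loc_t.notna().mean())

    if "shapes_transcriptome" in outputs and loc_t is not None:
        shapes = outputs["shapes_transcriptome"]
        shapes = shapes[shapes["shape"].astype(str).str.len() > 0]
        pred = loc_t.map(dict(zip(shapes["tc_id"], shapes["shape"])))
        mask = pred.notna()
        true_shape = truth.set_index("tc_key")["true_shape"][mask.index][mask]
        cm = pd.crosstab(true_shape, pred[mask].astype(str),
                         rownames=["true"], colnames=["predicted"])
        report["shape_confusion"] = cm
        report["shape_accuracy"] = float((true_shape.to_numpy()
                                          == pred[mask].to_numpy()).mean())

    if "tcdiff" in outputs and loc_p is not None and loc_t is not None:
        td = outputs["tcdiff"].copy()
        pair_of = {}
        for pid in td["pair_id"]:
            a, _, b = pid.partition("|")
            if a and b:
                pair_of[(a, b)] = pid
        log2fc_of = dict(zip(td["pair_id"], td["log2fc"]))
        true_fc_of = dict(zip(truth["tc_key"], truth["exp_log2fc"]))
        meas, true_vals = [], []
        for key in truth["tc_key"]:
            pid = pair_of.get((loc_p.get(key), loc_t.get(key)))
            if pid is None:
                continue
            val = log2fc_of[pid]
            if np.isfinite(val):
                meas.append(val)
                true_vals.append(true_fc_of[key])
        meas, true_vals = np.array(meas), np.array(true_vals)
        if len(meas):
            report["fc_bias"] = float((meas - true_vals).mean())
            report["fc_rmse"] = float(np.sqrt(((meas - true_vals) ** 2).mean()))
            report["fc_n"] = int(len(meas))

    if "disparity" in outputs and loc_p is not None and loc_t is not None:
        disp = outputs["disparity"]
        pair_truth = {}
        for key, sh in zip(truth["tc_key"], truth["shifted"]):
            a, b = loc_p.get(key), loc_t.get(key)
            if pd.notna(a) and pd.notna(b):
                pair_truth[(a, b)] = bool(sh)
        flags = []
        for row in disp.itertuples(index=False):
            t = pair_truth.get((row.tc_translatome, row.tc_transcriptome))
            if t is not None:
                flags.append((t, bool(row.changed)))
        if flags:
            arr = np.array(flags)
            pos = arr[:, 0]
            called = arr[:, 1]
            report["disparity_sensitivity"] = (
                float(called[pos].mean()) if pos.any() else np.nan)
            report["disparity_fdr"] = (
                float((~pos[called]).mean()) if called.any() else np.nan)
            report["disparity_n_tested"] = int(len(arr))

    if "gene_scores" in outputs:
        gs = outputs["gene_scores"].merge(bundle.gene_truth, on="gene")
        both = gs.dropna(subset=["S_du", "true_S_du"])
        if len(both):
            report["sdu_mae"] = float((both["S_du"] - both["true_S_du"]).abs().mean())
            report["sdu_n"] = int(len(both))
    return report


def scaled_config(seed: int = 1, n_genes: int = 1500,
                  library_size: int = 200_000, **overrides) -> SimConfig:
    """A smaller configuration for quick analyses and tests."""
    return replace(SimConfig(seed=seed, n_genes=n_genes,
                             library_size=(library_size, library_size)),
                   **overrides)
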