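"""End-to-end orchestration of the translatome/transcriptome comparison.

Stages are pure functions over files in ``out_dir`` so that ``run_all`` is
byte-for-byte the composition of the individual subcommands: cluster ->
annotate -> shapes/disparity -> differential/gene scores -> sequence
features.  Every emitted table carries ``#`` provenance headers naming the
parameters used.

From the TSS-selectivity stage onward the analysis is restricted to TCs
assigned to (extended) 5'UTRs, the TCs that act as core promoters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import clustering, differential, io_cage, promoter_annotation, seqfeat, shape_class


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline inputs and parameters.

    Thresholds default to the study's operating values: tag sets of >= 4
    tags form clusters, shapes need >= 100 tags, representative-TSS level
    comparisons need >= 10 tags at the representative TSS, and a TC is
    differential at |log2 FC| >= 1 with p < 0.05.
    """

    ctss_translatome: str = ""
    ctss_transcriptome: str = ""
    gtf: str = ""
    out_dir: str = "."
    fasta: str | None = None
    genome_length: int | None = None     # default: FASTA total, else GRCh37
    tag_length: int = 27
    min_tags: int = 4
    cluster_alpha: float = 0.001
    shape_min_tags: int = 100
    rep_tss_min: int = 10
    log2fc_threshold: float = 1.0
    alpha_diff: float = 0.05
    alpha_ks: float = 0.001
    group_k: int = 200
    seed: int = 1
    restrict_to_5utr: bool = True
    fc_trend_thresholds: tuple[float, ...] = (2, 4, 8, 16, 32)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.fc_trend_thresholds, list):
            cfg.fc_trend_thresholds = tuple(cfg.fc_trend_thresholds)
        return cfg

    def validate(self, need_gtf: bool = True) -> None:
        for name in ("ctss_translatome", "ctss_transcriptome") + (("gtf",) if need_gtf else ()):
            path = getattr(self, name)
            if not path:
                raise ConfigurationError(f"config field {name!r} is required")
            if not os.path.exists(path):
                raise ConfigurationError(f"{name}: no such file: {path}")
        if self.fasta and not os.path.exists(self.fasta):
            raise ConfigurationError(f"fasta: no such file: {self.fasta}")

    def params_header(self) -> dict:
        return {k: v for k, v in asdict(self).items()}

    def cluster_params(self, genome: io_cage.Genome | None = None
                       ) -> clustering.ClusterParams:
        # N is the background-model genome length, not the FASTA's literal
        # length: a synthetic genome holds only gene loci (no intergenic
        # deserts), so its length would not satisfy the uniform-background
        # assumption the Poisson rule models.
        N = self.genome_length if self.genome_length is not None else 3_095_693_983
        return clustering.ClusterParams(tag_length=self.tag_length,
                                        min_tags=self.min_tags,
                                        genome_length=N,
                                        alpha=self.cluster_alpha)


def _out(config: RunConfig, name: str) -> str:
    os.makedirs(config.out_dir, exist_ok=True)
    return os.path.join(config.out_dir, name)


def _library_size(clusters: list[clustering.TagCluster]) -> int:
    """Recover T from any cluster's stored (n, rpm); exact because rpm is
    serialized at full precision."""
    tc = clusters[0]
    return int(round(tc.n * 1e6 / tc.rpm))


def _load_genome(config: RunConfig) -> io_cage.Genome | None:
    return io_cage.read_fasta(config.fasta) if config.fasta else None


# ---------------------------------------------------------------------------
# stages


def stage_cluster(config: RunConfig) -> None:
    """Cluster both CTSS tables into tag-cluster tables."""
    config.validate(need_gtf=False)
    params = config.cluster_params()
    for label, path in (("translatome", config.ctss_translatome),
                        ("transcriptome", config.ctss_transcriptome)):
        records = io_cage.read_ctss(path)
        clusters = clustering.cluster_tags(records, params)
        io_cage.write_tc_table(
            clusters, _out(config, f"tc_{label}.tsv"),
            params={"sample": label, "min_tags": params.min_tags,
                    "tag_length": params.tag_length,
                    "genome_length": params.genome_length,
                    "library_size": int(records["count"].sum()),
                    "alpha": params.alpha})


def _load_clusters(config: RunConfig, label: str) -> list[clustering.TagCluster]:
    path = _out(config, f"tc_{label}.tsv")
    if not os.path.exists(path):
        raise ConfigurationError(f"missing stage output {path}; run `cluster` first")
    return io_cage.read_tc_table(path)


def stage_annotate(config: RunConfig) -> None:
    """Assign features / representative TSSs to both cluster sets."""
    config.validate()
    index = io_cage.read_annotation(config.gtf)
    genome = _load_genome(config)
    for label in ("translatome", "transcriptome"):
        clusters = _load_clusters(config, label)
        annotated = promoter_annotation.annotate_clusters(clusters, index, genome)
        frame = promoter_annotation.annotations_to_frame(annotated)
        io_cage.write_table(frame, _out(config, f"annotated_{label}.tsv"),
                            params={"sample": label, "gtf": config.gtf})


def _load_annotated(config: RunConfig, label: str) -> pd.DataFrame:
    path = _out(config, f"annotated_{label}.tsv")
    if not os.path.exists(path):
        raise ConfigurationError(f"missing stage output {path}; run `annotate` first")
    df = io_cage.read_table(path)
    for col in ("gene", "transcript", "first_nt", "feature"):
        df[col] = df[col].fillna("")
    return df


def _matched_5utr(config: RunConfig):
    """Shared plumbing: clusters, annotation maps and matched pairs, with
    the 5'UTR restriction applied (transcriptome feature governs when
    present)."""
    tcs = {label: _load_clusters(config, label)
           for label in ("translatome", "transcriptome")}
    ann = {label: _load_annotated(config, label).set_index("tc_id")
           for label in ("translatome", "transcriptome")}
    matched = shape_class.match_clusters(tcs["translatome"], tcs["transcriptome"])
    if config.restrict_to_5utr:
        feat_p = ann["translatome"]["feature"]
        feat_t = ann["transcriptome"]["feature"]
        matched = shape_class.MatchedPairs(
            pairs=[(a, b) for a, b in matched.pairs if feat_t[b.id] == "5utr"],
            only_a=[a for a in matched.only_a if feat_p[a.id] == "5utr"],
            only_b=[b for b in matched.only_b if feat_t[b.id] == "5utr"])
    return tcs, ann, matched


def stage_shape_disparity(config: RunConfig) -> None:
    """Shape classification, KS disparity and 5'UTR-length comparison."""
    config.validate()
    index = io_cage.read_annotation(config.gtf)
    tcs, ann, matched = _matched_5utr(config)

    shapes = {}
    for label in ("translatome", "transcriptome"):
        results = [shape_class.classify_shape(tc, config.shape_min_tags)
                   for tc in tcs[label]]
        frame = shape_class.shapes_to_frame(results)
        io_cage.write_table(frame, _out(config, f"shapes_{label}.tsv"),
                            params={"sample": label,
                                    "min_tags": config.shape_min_tags})
        shapes[label] = dict(zip(frame["tc_id"],
                                 frame["shape"].replace("", np.nan)))

    disparity = shape_class.ks_disparity(
        matched.pairs, min_tags=config.shape_min_tags, alpha=config.alpha_ks,
        shapes_a={k: v for k, v in shapes["translatome"].items() if pd.notna(v)},
        shapes_b={k: v for k, v in shapes["transcriptome"].items() if pd.notna(v)})
    io_cage.write_table(shape_class.disparity_to_frame(disparity),
                        _out(config, "disparity.tsv"),
                        params={"min_tags": config.shape_min_tags,
                                "alpha": config.alpha_ks})

    # representative-TSS level comparison (>= rep_tss_min tags at the rep TSS)
    rows = []
    ann_p, ann_t = ann["translatome"], ann["transcriptome"]
    for a, b in matched.pairs:
        ra, rb = ann_p.loc[a.id], ann_t.loc[b.id]
        if ra["rep_tss_count"] < config.rep_tss_min or rb["rep_tss_count"] < config.rep_tss_min:
            continue
        aa = promoter_annotation.AnnotatedCluster(
            a, ra["feature"], ra["gene"] or None, ra["transcript"] or None,
            int(ra["rep_tss"]), int(ra["rep_tss_count"]), ra["first_nt"] or None)
        ab = promoter_annotation.AnnotatedCluster(
            b, rb["feature"], rb["gene"] or None, rb["transcript"] or None,
            int(rb["rep_tss"]), int(rb["rep_tss_count"]), rb["first_nt"] or None)
        diff, status = promoter_annotation.utr_length_difference(aa, ab, index)
        rows.append((a.id, b.id, ra["gene"], aa.rep_tss, ab.rep_tss,
                     aa.rep_tss - ab.rep_tss,
                     aa.first_nt or "", ab.first_nt or "",
                     "" if diff is None else diff, status))
    utr = pd.DataFrame(rows, columns=[
        "tc_translatome", "tc_transcriptome", "gene", "rep_tss_translatome",
        "rep_tss_transcriptome", "rep_tss_distance", "first_nt_translatome",
        "first_nt_transcriptome", "utr_length_difference", "length_status"])
    io_cage.write_table(utr, _out(config, "utr_length.tsv"),
                        params={"rep_tss_min": config.rep_tss_min})


def stage_diff(config: RunConfig) -> None:
    """TC-level differential abundance, shape/FC trend and gene scores."""
    config.validate()
    tcs, ann, matched = _matched_5utr(config)
    T1 = _library_size(tcs["translatome"])
    T2 = _library_size(tcs["transcriptome"])

    triples = [(f"{a.id}|{b.id}", a.n, b.n) for a, b in matched.pairs]
    triples += [(f"{a.id}|", a.n, 0) for a in matched.only_a]
    triples += [(f"|{b.id}", 0, b.n) for b in matched.only_b]
    tcdiff = differential.tc_diff_table(triples, (T1, T2),
                                        config.log2fc_threshold,
                                        config.alpha_diff)
    io_cage.write_table(tcdiff, _out(config, "tc_diff.tsv"),
                        params={"T_translatome": T1, "T_transcriptome": T2,
                                "log2fc_threshold": config.log2fc_threshold,
                                "alpha": config.alpha_diff})

    # shape share vs minimal fold change among translatome-enriched TCs
    shapes_path = _out(config, "shapes_translatome.tsv")
    if os.path.exists(shapes_path):
        sh = io_cage.read_table(shapes_path)
        shape_of = {t: s for t, s in zip(sh["tc_id"], sh["shape"])
                    if isinstance(s, str) and s}
        enriched = tcdiff[tcdiff["status"] == "enriched"]
        fcs = {pid.split("|")[0]: fc
               for pid, fc in zip(enriched["pair_id"], enriched["fc"])}
        trend = shape_class.shape_fc_trend(shape_of, fcs,
                                           list(config.fc_trend_thresholds))
        trend["pearson_r_sp"] = trend.attrs["pearson_r_sp"]
        trend["pearson_r_bp"] = trend.attrs["pearson_r_bp"]
        io_cage.write_table(trend, _out(config, "shape_fc_trend.tsv"),
                            params={"thresholds": list(config.fc_trend_thresholds)})

    # gene scores over 5'UTR core promoters
    ann_p, ann_t = ann["translatome"], ann["transcriptome"]
    gene_promoters: dict[str, list[tuple[float, float, int, int]]] = {}
    for a, b in matched.pairs:
        gene = ann_t.loc[b.id, "gene"] or ann_p.loc[a.id, "gene"]
        if gene:
            gene_promoters.setdefault(gene, []).append(
                (a.n / T1 * 1e6, b.n / T2 * 1e6, a.n, b.n))
    for a in matched.only_a:
        gene = ann_p.loc[a.id, "gene"]
        if gene:
            gene_promoters.setdefault(gene, []).append((a.n / T1 * 1e6, 0.0, a.n, 0))
    for b in matched.only_b:
        gene = ann_t.loc[b.id, "gene"]
        if gene:
            gene_promoters.setdefault(gene, []).append((0.0, b.n / T2 * 1e6, 0, b.n))

    scores = differential.gene_scores(gene_promoters, (T1, T2),
                                      config.log2fc_threshold, config.alpha_diff)
    frame = differential.gene_scores_to_frame(scores)
    io_cage.write_table(frame, _out(config, "gene_scores.tsv"),
                        params={"T_translatome": T1, "T_transcriptome": T2})
    sdu = frame[(frame["n_promoters"] >= 2) & frame["S_du"].notna()]
    io_cage.write_table(
        sdu[["gene", "n_promoters", "E_p", "E_t", "S_fc", "S_du"]],
        _out(config, "gene_sdu.tsv"), params={})


def stage_seqfeat(config: RunConfig) -> None:
    """GC/AUG/TATA statistics of enriched vs depleted vs control TCs."""
    config.validate(need_gtf=False)
    genome = _load_genome(config)
    if genome is None:
        raise ConfigurationError("seqfeat stage requires a genome FASTA")
    tcdiff_path = _out(config, "tc_diff.tsv")
    if not os.path.exists(tcdiff_path):
        raise ConfigurationError("missing tc_diff.tsv; run `diff` first")
    tcdiff = io_cage.read_table(tcdiff_path)
    ann_p = _load_annotated(config, "translatome").set_index("tc_id")
    ann_t = _load_annotated(config, "transcriptome").set_index("tc_id")

    groups = seqfeat.pick_groups(tcdiff, k=config.group_k, seed=config.seed)

    def _sites(sub: pd.DataFrame) -> list[tuple[str, int, str]]:
        sites = []
        for pid in sub["pair_id"]:
            id_a, _, id_b = pid.partition("|")
            row = ann_p.loc[id_a] if id_a else ann_t.loc[id_b]
            sites.append((row["chrom"], int(row["rep_tss"]), row["strand"]))
        return sites

    down = {lab: seqfeat.extract_windows(lab, _sites(sub), genome, "downstream")
            for lab, sub in groups.items()}
    up = {lab: seqfeat.extract_windows(lab, _sites(sub), genome, "upstream")
          for lab, sub in groups.items()}
    stats = seqfeat.group_stats(down, up)
    tata = seqfeat.tata_enrichment(up["enriched"], up["control"])
    stats["tata_fold_vs_control"] = [tata["fold"] if lab == "enriched" else np.nan
                                     for lab in stats["group"]]
    io_cage.write_table(stats, _out(config, "seqfeat_stats.tsv"),
                        params={"k": config.group_k, "seed": config.seed,
                                "tata_pattern": seqfeat.TATA_PATTERN})
    for lab, ws in down.items():
        seqfeat.write_group_fasta(ws, _out(config, f"windows_{lab}_downstream.fa"))


STAGES = (stage_cluster, stage_annotate, stage_shape_disparity, stage_diff,
          stage_seqfeat)


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage in order and return the main output tables."""
    config.validate()
    for stage in STAGES:
        if stage is stage_seqfeat and not config.fasta:
            continue
        stage(config)
    out = {}
    for name in ("disparity", "utr_length", "tc_diff", "gene_scores",
                 "gene_sdu", "shape_fc_trend"):
        path = _out(config, f"{name}.tsv")
        if os.path.exists(path):
            out[name] = io_cage.read_table(path)
    return out
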