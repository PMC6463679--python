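#!/usr/bin/env python
"""Quantify polysome selection: per-promoter differential abundance
(exact two-library binomial test, |log2 FC| >= 1 and p < 0.05), the shape
class vs fold-change trend, and the gene-level S_fc / S_du scores."""

import os

import numpy as np
from scipy import stats

from cagesel import io_cage, pipeline

from common import results_path, run_config


def main() -> None:
    cfg = run_config()
    pipeline.stage_diff(cfg)

    td = io_cage.read_table(os.path.join(cfg.out_dir, "tc_diff.tsv"))
    tested = td[td["status"] != ""]
    sig = td["status"].isin(["enriched", "depleted"]).sum()
    print(f"core-promoter pairs tested: {len(tested):,}; "
          f"{sig:,} ({sig / len(tested):.1%}) significantly changed "
          f"(|log2FC| >= {cfg.log2fc_threshold:g}, p < {cfg.alpha_diff})")
    n_enr = (td["status"] == "enriched").sum()
    print(f"of these, {n_enr:,} ({n_enr / max(sig, 1):.1%}) are translatome-enriched")

    trend = io_cage.read_table(os.path.join(cfg.out_dir, "shape_fc_trend.tsv"))
    print("shape share vs minimal fold change (translatome-enriched TCs):")
    print(trend[["min_fc", "n_tc", "pct_sp", "pct_bp"]].to_string(index=False))
    print(f"Pearson R: SP {trend['pearson_r_sp'].iloc[0]:+.2f}, "
          f"BP {trend['pearson_r_bp'].iloc[0]:+.2f}")
    print("(the generator plants shape and fold change independently, so the"
          " SP/BP shares should stay roughly flat across cutoffs here;"
          " a real shape-selection signal would show a monotone trend)")

    gs = io_cage.read_table(os.path.join(cfg.out_dir, "gene_scores.tsv"))
    sig_genes = gs["significant"].sum()
    print(f"genes scored: {len(gs):,}; {sig_genes:,} ({sig_genes / len(gs):.1%}) "
          "significantly enriched or depleted in translatome")
    sdu = io_cage.read_table(os.path.join(cfg.out_dir, "gene_sdu.tsv"))
    print(f"genes with >= 2 core promoters (S_du defined): {len(sdu):,}; "
          f"{(sdu['S_du'] > 0.5).sum():,} with S_du > 0.5")
    both = gs[(gs["n_promoters"] >= 2) & gs["S_du"].notna()
              & np.isfinite(gs["log2_S_fc"])]
    r, _ = stats.pearsonr(both["S_du"], both["log2_S_fc"])
    print(f"Pearson R(S_du, log2 S_fc) = {r:+.3f} over {len(both):,} genes "
          "(usage change is independent of abundance change)")

    gs.sort_values("q_value").head(200).to_csv(
        results_path("gene_scores_top.tsv"), sep="\t", index=False)
    sdu.sort_values("S_du", ascending=False).head(200).to_csv(
        results_path("gene_sdu_top.tsv"), sep="\t", index=False)
    print("wrote", results_path("gene_scores_top.tsv"), "and",
          results_path("gene_sdu_top.tsv"))


if __name__ == "__main__":
    main()
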