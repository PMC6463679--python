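#!/usr/bin/env python
"""Shape-classify the tag clusters and test translatome-vs-transcriptome
5'-end distribution disparity (two-sample KS on matched >=100-tag
clusters), plus representative-TSS level comparisons: first-nucleotide
frequencies and 5'UTR length differences."""

import os

import pandas as pd

from cagesel import io_cage, pipeline

from common import results_path, run_config


def main() -> None:
    cfg = run_config()
    pipeline.stage_shape_disparity(cfg)

    for label in ("translatome", "transcriptome"):
        sh = io_cage.read_table(os.path.join(cfg.out_dir, f"shapes_{label}.tsv"))
        classified = sh[sh["shape"].notna() & (sh["shape"] != "")]
        print(f"{label}: {len(classified):,} clusters with >= {cfg.shape_min_tags} "
              f"tags classified:",
              classified["shape"].value_counts(normalize=True).round(3).to_dict())

    disp = io_cage.read_table(os.path.join(cfg.out_dir, "disparity.tsv"))
    changed = disp["changed"].sum()
    print(f"KS disparity: {len(disp):,} matched core-promoter pairs tested; "
          f"{changed:,} ({changed / len(disp):.1%}) changed at p < {cfg.alpha_ks}")
    cls_change = disp[disp["changed"]
                      & (disp["shape_translatome"] != disp["shape_transcriptome"])]
    print(f"of the changed pairs, {len(cls_change):,} also switch shape class")

    utr = io_cage.read_table(os.path.join(cfg.out_dir, "utr_length.tsv"))
    moved = (utr["rep_tss_distance"] != 0).sum()
    print(f"representative TSSs (>= {cfg.rep_tss_min} tags): {len(utr):,} pairs; "
          f"{moved:,} ({moved / len(utr):.1%}) use a different position")
    nt_changed = (utr["first_nt_translatome"] != utr["first_nt_transcriptome"]).sum()
    print(f"{nt_changed:,} ({nt_changed / len(utr):.1%}) change the first nucleotide")
    freqs = pd.DataFrame({
        "translatome": utr["first_nt_translatome"].value_counts(normalize=True),
        "transcriptome": utr["first_nt_transcriptome"].value_counts(normalize=True),
    }).round(4)
    freqs.index.name = "base"
    freqs.to_csv(results_path("first_nt_frequencies.tsv"), sep="\t")
    print("first-nucleotide frequencies written to",
          results_path("first_nt_frequencies.tsv"))
    disp.head(500).to_csv(results_path("disparity_top.tsv"), sep="\t", index=False)
    print("status counts of 5'UTR length:",
          utr["length_status"].value_counts().to_dict())


if __name__ == "__main__":
    main()
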