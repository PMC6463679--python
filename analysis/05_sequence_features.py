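#!/usr/bin/env python
"""Sequence context of polysome selection: GC content and AUG counts in
the 100 nt downstream of representative TSSs, and TATA-box enrichment in
the 100 nt upstream, comparing top-enriched, top-depleted and
FC-matched control promoters."""

import os

from cagesel import io_cage, pipeline

from common import results_path, run_config


def main() -> None:
    cfg = run_config()
    pipeline.stage_seqfeat(cfg)

    stats = io_cage.read_table(os.path.join(cfg.out_dir, "seqfeat_stats.tsv"))
    print(stats.to_string(index=False))
    by = stats.set_index("group")
    print(f"GC: enriched {by.loc['enriched', 'gc_fraction']:.3f} < "
          f"control {by.loc['control', 'gc_fraction']:.3f} < "
          f"depleted {by.loc['depleted', 'gc_fraction']:.3f} (planted gradient)")
    print(f"AUG totals: enriched {by.loc['enriched', 'aug_total']} vs "
          f"depleted {by.loc['depleted', 'aug_total']} vs "
          f"control {by.loc['control', 'aug_total']}")
    fold = by.loc["enriched", "tata_fold_vs_control"]
    print(f"TATA-box enrichment (enriched vs control upstream windows): "
          f"{fold:.1f}-fold")
    stats.to_csv(results_path("seqfeat_stats.tsv"), sep="\t", index=False)
    print("wrote", results_path("seqfeat_stats.tsv"))


if __name__ == "__main__":
    main()
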