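#!/usr/bin/env python
"""Score every pipeline stage against the generator's truth key: cluster
recovery, shape confusion, fold-change bias/RMSE, disparity sensitivity
and FDR, and S_du error."""

import os

import pandas as pd

from cagesel import io_cage, synthetic_data as sd

from common import OUT_DIR, load_bundle, results_path


def main() -> None:
    bundle = load_bundle()
    outputs = {
        "annotated_translatome": io_cage.read_table(
            os.path.join(OUT_DIR, "annotated_translatome.tsv")),
        "annotated_transcriptome": io_cage.read_table(
            os.path.join(OUT_DIR, "annotated_transcriptome.tsv")),
        "shapes_transcriptome": io_cage.read_table(
            os.path.join(OUT_DIR, "shapes_transcriptome.tsv")),
        "disparity": io_cage.read_table(os.path.join(OUT_DIR, "disparity.tsv")),
        "tcdiff": io_cage.read_table(os.path.join(OUT_DIR, "tc_diff.tsv")),
        "gene_scores": io_cage.read_table(os.path.join(OUT_DIR, "gene_scores.tsv")),
    }
    report = sd.truth_compare(outputs, bundle)

    cm = report.pop("shape_confusion")
    print("shape confusion matrix (true x predicted):")
    print(cm)
    cm.to_csv(results_path("shape_confusion.tsv"), sep="\t")
    scalars = pd.Series(report).round(4)
    print(scalars.to_string())
    scalars.rename("value").to_frame().to_csv(
        results_path("truth_recovery.tsv"), sep="\t")
    print("wrote", results_path("truth_recovery.tsv"))


if __name__ == "__main__":
    main()
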