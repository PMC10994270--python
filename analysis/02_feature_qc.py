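#!/usr/bin/env python
"""Feature QC: well-level aggregation, robust per-plate normalization
against the knock-out vehicle wells, removal of degenerate and redundant
variables, and the per-feature one-way ANOVA (BH FDR) across treatment
classes.  Writes the filtered well-level table, the normalized
image-level table (for later image-level classification) and the QC
report."""

from pathlib import Path

from morphoscreen.io import read_feature_table, write_feature_table
from morphoscreen.qc import normalize_to_controls, run_qc

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    image = read_feature_table(OUT / "image_features.csv")
    well, report = run_qc(image)
    report.to_json(OUT / "qc_report.json")
    write_feature_table(well, OUT / "well_features_qc.csv")

    norm_images, _ = normalize_to_controls(image)
    norm_images = norm_images[
        [c for c in ("plate_id", "well", "subclone_id", "genotype", "treatment",
                     "concentration_nM", "field") if c in norm_images.columns]
        + report.feature_names
    ]
    write_feature_table(norm_images, OUT / "image_features_norm.csv")

    print(f"features: {report.n_input_features} in -> {report.n_retained} retained "
          f"({len(report.dropped_degenerate)} degenerate, "
          f"{len(report.dropped_redundant)} redundant dropped)")
    print(f"ANOVA across treatment classes: {report.n_significant} features "
          f"significant at q < {report.alpha} "
          f"({len(report.untestable)} untestable)")


if __name__ == "__main__":
    main()
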