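#!/usr/bin/env python
"""Generate the default synthetic screen.

Nine 384-well plates (3 knock-out sub-clones x 3 concentrations), 330
library compounds at one well per plate, 24 wild-type vehicle wells, 16
knock-out vehicle wells and 6 untreated knock-out wells per plate, 4
image fields per well, 1100 correlated morphological features.  Ten
compounds are planted as true reverters (reversion rho >= 0.8), among
them both salt-form pairs.  Writes the image-level feature table, the
ground truth and the library manifest under results/screen/.
"""

import argparse
from pathlib import Path

from morphoscreen.design import build_design
from morphoscreen.manifest import default_library_manifest, write_manifest
from morphoscreen.pipeline import stage_seeds
from morphoscreen.simulate import SimulationParams, simulate_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    design = build_design()
    params = SimulationParams(seed=stage_seeds(args.seed)["simulate"])
    table, truth = simulate_screen(design, params)
    manifest = default_library_manifest()

    table.to_csv(OUT / "image_features.csv", index=False, float_format="%.6g")
    truth.to_json(OUT / "ground_truth.json")
    write_manifest(manifest, OUT / "manifest.csv")

    print(f"screen: {design.n_plates} plates x {design.wells_per_plate} wells "
          f"x {design.fields_per_well} fields = {len(table)} image records, "
          f"{params.n_features} features")
    print(f"planted reverters ({len(truth.true_hits)}): {', '.join(truth.true_hits)}")
    print(f"wrote {OUT}/image_features.csv, ground_truth.json, manifest.csv")


if __name__ == "__main__":
    main()
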