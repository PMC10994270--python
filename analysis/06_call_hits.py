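#!/usr/bin/env python
"""Replicated hit calling: a compound is a hit when its wild-type
similarity score exceeds 0.505 in all three knock-out sub-clones at one
or more concentrations.  Salt formulations of the same parent drug are
collapsed, hits are grouped by mechanism class, and the called set is
compared against the simulation ground truth."""

import argparse
from pathlib import Path

import pandas as pd

from morphoscreen.hits import (
    call_hits,
    collapse_salt_forms,
    recovery_vs_truth,
    summarize_by_mechanism,
)
from morphoscreen.manifest import read_manifest
from morphoscreen.simulate import GroundTruth

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--threshold", type=float, default=0.505)
    parser.add_argument("--mode", default="any_conc", choices=["any_conc", "same_conc"])
    args = parser.parse_args()

    scores = pd.read_csv(OUT / "treated_scores.csv")
    manifest = read_manifest(OUT / "manifest.csv")
    truth = GroundTruth.from_json(OUT / "ground_truth.json")

    hit_table = call_hits(scores, tau=args.threshold, mode=args.mode)
    hit_table.to_csv(OUT / "hit_table.csv", index=False)
    drugs = collapse_salt_forms(hit_table, manifest)
    drugs.to_csv(OUT / "drug_hits.csv", index=False)
    mech = summarize_by_mechanism(drugs, manifest)
    mech.to_csv(OUT / "mechanism_summary.csv", index=False)

    hits = sorted(hit_table.loc[hit_table["hit"], "compound_id"])
    print(f"hits (> {args.threshold}, {args.mode}, replicated in 3 sub-clones): "
          f"{len(hits)} compounds -> {len(drugs)} unique drugs after salt collapse")
    print(f"  {', '.join(hits)}")
    if len(mech):
        for _, row in mech.iterrows():
            print(f"  {row['mechanism_class']}: {row['n_drugs']} drug(s), "
                  f"best score {row['max_score']:.3f}")
    rec = recovery_vs_truth(hit_table, truth.true_hits)
    print(f"vs ground truth: {rec['true_positives']}/{rec['n_true_reverters']} "
          f"planted reverters recovered, {rec['false_positives']} false positives "
          f"among {rec['true_negatives'] + rec['false_positives']} non-reverters")


if __name__ == "__main__":
    main()
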