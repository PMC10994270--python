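#!/usr/bin/env python
"""Control-anchored classification and compound scoring.

Trains the three-layer neural network (hidden size and weight decay
chosen by two-fold cross-validation) on 80% of the vehicle-treated
control wells at image level, evaluates the confusion matrix on the
held-out 20%, then scores every compound-treated well by the median
image-level probability of classifying as wild-type."""

import argparse
from pathlib import Path

import pandas as pd

from morphoscreen.classify import (
    ClassifierSpec,
    evaluate_classifier,
    score_treated,
    split_controls,
    train_classifier,
)
from morphoscreen.pipeline import stage_seeds

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--algorithm", default="nn", choices=["nn", "rf", "svm"])
    args = parser.parse_args()

    scores = pd.read_csv(OUT / "image_scores.csv")
    spec = ClassifierSpec(algorithm=args.algorithm,
                          seed=stage_seeds(args.seed)["train"])
    controls = scores[scores["treatment"] == "VEHICLE"]
    train, test = split_controls(controls, spec)
    model = train_classifier(train, spec)
    report = evaluate_classifier(model, test)
    report.to_json(OUT / f"classifier_report_{args.algorithm}.json")

    print(f"{args.algorithm}: hyper-parameters size={report.chosen_size}, "
          f"decay={report.chosen_decay}")
    print(f"held-out confusion matrix: TP={report.tp} FP={report.fp} "
          f"TN={report.tn} FN={report.fn}")
    print(f"sensitivity={report.sensitivity:.4f} specificity={report.specificity:.4f} "
          f"detection rate={report.detection_rate:.4f} accuracy={report.accuracy:.4f}")
    print(f"mean wild-type probability: WT wells "
          f"{report.mean_focus_probability['WT']:.4f}, KO wells "
          f"{report.mean_focus_probability['KO']:.4f}")

    treated = scores[~scores["treatment"].isin(["VEHICLE", "UNTREATED"])]
    well_scores = score_treated(model, treated)
    well_scores.to_csv(OUT / "treated_scores.csv", index=False)
    print(f"scored {well_scores['compound_id'].nunique()} compounds across "
          f"{len(well_scores)} wells -> treated_scores.csv")


if __name__ == "__main__":
    main()
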