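"""Replicated hit calling, salt-form collapse and mechanism grouping.

A compound is a hit when its wild-type-similarity score strictly exceeds
the threshold tau (default 0.505) in every knock-out sub-clone at one or
more concentrations.  Hits sharing a parent drug (salt formulations) are
collapsed to unique drug treatments, then grouped by annotated mechanism
class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_TAU = 0.505
MODES = ("any_conc", "same_conc")


class ManifestCoverageError(KeyError):
    """A hit compound is absent from the library manifest."""


def call_hits(
    scores: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    mode: str = "any_conc",
) -> pd.DataFrame:
    """Per-compound hit flags from the (sub-clone x concentration) scores.

    Parameters
    ----------
    scores
        Long table with columns compound_id, subclone_id,
        concentration_nM, score.  Multiple wells per cell are reduced to
        their maximum.  Missing cells count as non-exceeding.
    tau
        Strict threshold: a score of exactly tau is never a hit.
    mode
        "any_conc": each sub-clone must exceed tau at >= 1 (possibly
        different) concentration.  "same_conc": one single concentration
        must exceed tau in every sub-clone.

    Returns a frame per compound: max_score, hit, plus one column per
    (sub-clone, concentration) cell.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    cell = (
        scores.groupby(["compound_id", "subclone_id", "concentration_nM"])["score"]
        .max()
        .unstack(["subclone_id", "concentration_nM"])
    )
    exceed = cell > tau  # NaN (missing cell) compares False: non-exceeding
    if mode == "any_conc":
        hit = exceed.T.groupby(level="subclone_id").any().all(axis=0)
    else:
        hit = exceed.T.groupby(level="concentration_nM").all().any(axis=0)
    wide = cell.copy()
    wide.columns = [f"{sc}@{int(conc)}nM" for sc, conc in wide.columns]
    out = wide.reset_index()
    out.insert(1, "max_score", cell.max(axis=1).to_numpy())
    out.insert(2, "hit", hit.reindex(cell.index).to_numpy())
    out.attrs["tau"] = tau
    out.attrs["mode"] = mode
    return out


def collapse_salt_forms(hit_table: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Merge hit compounds sharing a parent drug into unique drug rows.

    Keeps the best score per drug and records which compound ids
    contributed.  Raises ManifestCoverageError for a hit compound the
    manifest does not annotate.
    """
    hits = hit_table[hit_table["hit"]]
    lookup = manifest.set_index("compound_id")
    missing = [c for c in hits["compound_id"] if c not in lookup.index]
    if missing:
        raise ManifestCoverageError(f"hit compounds absent from manifest: {missing}")
    if len(hits) == 0:
        return pd.DataFrame(
            columns=["parent_drug", "mechanism_class", "best_score", "n_forms", "compound_ids"]
        )
    joined = hits.merge(
        manifest[["compound_id", "parent_drug", "mechanism_class"]], on="compound_id"
    )
    out = (
        joined.groupby("parent_drug", sort=True)
        .agg(
            mechanism_class=("mechanism_class", "first"),
            best_score=("max_score", "max"),
            n_forms=("compound_id", "nunique"),
            compound_ids=("compound_id", lambda s: ",".join(sorted(s))),
        )
        .reset_index()
    )
    out.attrs["n_compound_hits"] = int(len(hits))
    out.attrs["n_drug_hits"] = int(len(out))
    return out


def summarize_by_mechanism(drug_table: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-mechanism-class drug counts and score summaries.

    Drugs without an annotation are counted under "unannotated".
    """
    if len(drug_table) == 0:
        return pd.DataFrame(columns=["mechanism_class", "n_drugs", "mean_score", "max_score"])
    t = drug_table.copy()
    cls = t["mechanism_class"].astype(object)
    cls = cls.where(cls.notna() & (cls != ""), "unannotated")
    t["mechanism_class"] = cls
    return (
        t.groupby("mechanism_class", sort=True)
        .agg(
            n_drugs=("parent_drug", "nunique"),
            mean_score=("best_score", "mean"),
            max_score=("best_score", "max"),
        )
        .reset_index()
    )


def recovery_vs_truth(hit_table: pd.DataFrame, true_hits: list[str]) -> dict:
    """Sensitivity/false positives of the called hits against ground truth."""
    called = set(hit_table.loc[hit_table["hit"], "compound_id"])
    truth = set(true_hits)
    all_compounds = set(hit_table["compound_id"])
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = len(all_compounds - called - truth)
    return {
        "n_true_reverters": len(truth),
        "n_called_hits": len(called),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "true_negatives": tn,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
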