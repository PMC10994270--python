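"""Well aggregation, control-anchored normalization and feature filtering.

Fixed pipeline order: aggregate -> normalize -> drop_degenerate ->
drop_redundant -> anova_filter.  Re-running the filters on their own
output drops nothing further.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import METADATA_COLUMNS
from .io import feature_columns, metadata_columns

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normal data


class ConsistencyError(ValueError):
    """Metadata disagrees within an aggregation unit."""


class MissingControlsError(ValueError):
    """A plate lacks the anchor control wells."""


@dataclass
class QCReport:
    """Outcome of the feature-filtering stages."""

    n_input_features: int
    dropped_degenerate: list[str]
    dropped_redundant: list[str]
    n_retained: int
    feature_names: list[str] = field(default_factory=list)
    f_statistic: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    q_value: dict[str, float] = field(default_factory=dict)
    untestable: list[str] = field(default_factory=list)
    n_significant: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        n_dropped = len(self.dropped_degenerate) + len(self.dropped_redundant)
        if self.n_input_features != self.n_retained + n_dropped:
            raise ValueError("n_input != n_retained + dropped")
        if set(self.dropped_degenerate) & set(self.dropped_redundant):
            raise ValueError("dropped lists overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def aggregate_to_well(table: pd.DataFrame, statistic: str = "median") -> pd.DataFrame:
    """Collapse image-field records to one record per well.

    Missing field values are ignored by the aggregation statistic.  All
    non-field metadata must be constant within a well.
    """
    if "field" not in table.columns:
        raise ValueError("table has no 'field' column; already well-level?")
    feats = feature_columns(table)
    meta = [c for c in metadata_columns(table) if c != "field"]
    key = ["plate_id", "well"]
    other_meta = [c for c in meta if c not in key]
    grouped = table.groupby(key, sort=False)
    bad = grouped[other_meta].nunique()
    inconsistent = bad[(bad > 1).any(axis=1)]
    if len(inconsistent):
        raise ConsistencyError(
            f"metadata varies within wells: {inconsistent.index.tolist()[:5]}"
        )
    if statistic not in ("median", "mean"):
        raise ValueError(f"unsupported statistic {statistic!r}")
    agg = grouped.agg({**{c: "first" for c in other_meta}, **{c: statistic for c in feats}})
    out = agg.reset_index()[meta + feats]
    out.attrs["aggregation"] = statistic
    return out


def normalize_to_controls(
    table: pd.DataFrame, anchor: str = "ko_vehicle"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-plate robust z-scoring against control wells.

    Each feature is centred on the anchor wells' median and scaled by
    1.4826 x their MAD, plate by plate.  The default anchor is the
    knock-out vehicle wells (the mutant baseline), so a positive
    displacement along the genotype axis reads as movement toward the
    wild-type; ``anchor='wt_vehicle'`` is provided as an option.

    Returns the normalized table and the list of features whose MAD was
    zero on at least one plate; those are centred but never divided.
    """
    if anchor == "ko_vehicle":
        mask = (table["genotype"] == "KO") & (table["treatment"] == "VEHICLE")
    elif anchor == "wt_vehicle":
        mask = (table["genotype"] == "WT") & (table["treatment"] == "VEHICLE")
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    feats = feature_columns(table)
    out = table.copy()
    X = out[feats].to_numpy(dtype=float)
    degenerate = np.zeros(len(feats), dtype=bool)

    plate_stats = {}
    for plate, idx in table.groupby("plate_id", sort=False).groups.items():
        ctrl_idx = idx[mask.loc[idx].to_numpy()]
        if len(ctrl_idx) < 4:
            raise MissingControlsError(
                f"plate {plate} has {len(ctrl_idx)} {anchor} wells (need >= 4)"
            )
        C = table.loc[ctrl_idx, feats].to_numpy(dtype=float)
        med = np.nanmedian(C, axis=0)
        mad = np.nanmedian(np.abs(C - med), axis=0) * MAD_SCALE
        degenerate |= mad == 0
        plate_stats[plate] = (med, mad)

    pos = {p: np.flatnonzero((table["plate_id"] == p).to_numpy()) for p in plate_stats}
    for plate, (med, mad) in plate_stats.items():
        safe = np.where(mad == 0, 1.0, mad)
        X[pos[plate]] = (X[pos[plate]] - med) / np.where(degenerate, 1.0, safe)
    out[feats] = X
    return out, [f for f, d in zip(feats, degenerate) if d]


def drop_degenerate(
    table: pd.DataFrame, rank_tol: float = 1e-8
) -> tuple[pd.DataFrame, list[str]]:
    """Remove zero-variance columns, then columns linearly dependent on
    earlier retained ones (sequential Gram-Schmidt with relative
    tolerance ``rank_tol``)."""
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)

    dropped: list[str] = []
    keep: list[int] = []
    Q = np.empty((n, len(feats)))
    k = 0
    for j, name in enumerate(feats):
        c = Xc[:, j]
        norm = np.linalg.norm(c)
        if norm == 0 or np.var(X[:, j]) == 0:
            dropped.append(name)
            continue
        r = c - Q[:, :k] @ (Q[:, :k].T @ c) if k else c.copy()
        # one re-orthogonalization pass for numerical safety
        if k:
            r -= Q[:, :k] @ (Q[:, :k].T @ r)
        rnorm = np.linalg.norm(r)
        if rnorm <= rank_tol * norm:
            dropped.append(name)
            continue
        Q[:, k] = r / rnorm
        k += 1
        keep.append(j)
    if not keep:
        warnings.warn("all features degenerate; empty feature set")
    kept_names = [feats[j] for j in keep]
    meta = metadata_columns(table)
    return table[meta + kept_names], dropped


def drop_redundant(
    table: pd.DataFrame, r_threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively remove one member of each highly correlated pair.

    While any pair has |Pearson r| >= threshold, the member with the
    larger mean absolute correlation to all other active features is
    dropped; ties drop the lexicographically later name.
    """
    feats = feature_columns(table)
    if len(feats) < 2:
        return table, []
    C = np.abs(np.corrcoef(table[feats].to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(C, 0.0)
    active = np.ones(len(feats), dtype=bool)
    dropped: list[str] = []
    while True:
        sub = np.where(active[:, None] & active[None, :], C, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < r_threshold:
            break
        n_active = active.sum()
        mean_i = sub[i].sum() / (n_active - 1)
        mean_j = sub[j].sum() / (n_active - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = i if feats[i] > feats[j] else j
        active[drop] = False
        dropped.append(feats[drop])
    kept = [f for f, a in zip(feats, active) if a]
    meta = metadata_columns(table)
    return table[meta + kept], sorted(dropped, key=feats.index)


def anova_filter(
    table: pd.DataFrame, group_labels: pd.Series | np.ndarray, alpha: float = 0.05,
    dropped_degenerate: list[str] | None = None,
    dropped_redundant: list[str] | None = None,
    n_input_features: int | None = None,
) -> QCReport:
    """Per-feature one-way ANOVA across groups with BH FDR correction.

    Groups are treatment classes (wild-type vehicle, knock-out vehicle,
    each compound treatment, ...).  Features constant in every
    observation are flagged untestable and excluded from the correction.
    """
    labels = np.asarray(group_labels)
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 observations: {small.tolist()}")

    groups = [X[labels == u] for u in uniq]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups, axis=0)

    untestable = ~np.isfinite(p)
    # between-group signal with zero within-group variance: certain difference
    sure = np.isinf(F) & ~np.isfinite(p)
    p = np.where(sure, 0.0, p)
    untestable &= ~sure

    testable = ~untestable
    q = np.full(len(feats), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    sig = int(np.sum(q[testable] < alpha))

    dd = dropped_degenerate or []
    dr = dropped_redundant or []
    n_input = n_input_features if n_input_features is not None else len(feats) + len(dd) + len(dr)
    return QCReport(
        n_input_features=n_input,
        dropped_degenerate=dd,
        dropped_redundant=dr,
        n_retained=len(feats),
        feature_names=feats,
        f_statistic={f: float(F[i]) for i, f in enumerate(feats) if testable[i]},
        p_value={f: float(p[i]) for i, f in enumerate(feats) if testable[i]},
        q_value={f: float(q[i]) for i, f in enumerate(feats) if testable[i]},
        untestable=[f for i, f in enumerate(feats) if untestable[i]],
        n_significant=sig,
        alpha=alpha,
    )


def run_qc(
    image_table: pd.DataFrame,
    anchor: str = "ko_vehicle",
    rank_tol: float = 1e-8,
    r_threshold: float = 0.95,
    alpha: float = 0.05,
    statistic: str = "median",
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain on an image-level table.

    Returns the normalized, filtered well-level table and a QCReport
    whose ANOVA compares treatment classes (genotype x treatment label).
    """
    n_input = len(feature_columns(image_table))
    well = aggregate_to_well(image_table, statistic=statistic)
    norm, mad_degenerate = normalize_to_controls(well, anchor=anchor)
    kept = [c for c in norm.columns if c not in mad_degenerate]
    norm = norm[kept]
    dedup, gs_degenerate = drop_degenerate(norm, rank_tol=rank_tol)
    slim, redundant = drop_redundant(dedup, r_threshold=r_threshold)
    labels = slim["genotype"].str.cat(slim["treatment"], sep="_")
    report = anova_filter(
        slim,
        labels,
        alpha=alpha,
        dropped_degenerate=sorted(set(mad_degenerate) | set(gs_degenerate)),
        dropped_redundant=redundant,
        n_input_features=n_input,
    )
    return slim, report
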