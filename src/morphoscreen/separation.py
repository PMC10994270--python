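"""Phenotypic separation between labelled groups in signature space.

The separation statistic D is the ratio of the mean between-group
dissimilarity to the mean within-group dissimilarity (D > 1 indicates
separation), with a label-permutation p-value.  Bray-Curtis requires
non-negative profiles, so each component is min-max rescaled to [0, 1]
across the compared profiles first — the rescaling depends only on the
pooled profiles, never on the labels, so it is fixed under permutation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

METRICS = ("bray_curtis", "euclidean")


@dataclass
class SeparationResult:
    metric: str
    statistic: float          # D = mean between / mean within
    p_value: float
    n_perm: int
    seed: int
    group_sizes: dict[str, int]
    observed_infinite: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def pairwise_dissimilarity(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    """Euclidean distance or Bray-Curtis dissimilarity of two profiles.

    Bray-Curtis expects non-negative inputs (e.g. min-max rescaled
    component scores); an all-zero denominator is defined as 0 with a
    warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((u - v) ** 2)))
    if metric == "bray_curtis":
        denom = float(np.sum(u + v))
        if denom == 0:
            warnings.warn("Bray-Curtis with all-zero denominator; returning 0")
            return 0.0
        return float(np.sum(np.abs(u - v)) / denom)
    raise ValueError(f"unknown metric {metric!r}")


def minmax_rescale(X: np.ndarray) -> np.ndarray:
    """Per-column (x - min) / (max - min); constant columns -> 0 with warning."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    if np.any(span == 0):
        warnings.warn(f"{int(np.sum(span == 0))} constant component(s) rescaled to 0")
    safe = np.where(span == 0, 1.0, span)
    out = (X - lo) / safe
    out[:, span == 0] = 0.0
    return out


def _dissimilarity_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Full pairwise matrix, computed from the definitions (vectorized)."""
    if metric == "euclidean":
        sq = np.sum(X**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
        return np.sqrt(np.clip(d2, 0.0, None))
    if metric == "bray_curtis":
        num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
        if np.any(den == 0):
            warnings.warn("Bray-Curtis pairs with all-zero denominator set to 0")
        return np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    raise ValueError(f"unknown metric {metric!r}")


def _prepare(profiles: np.ndarray, labels: np.ndarray, metric: str):
    X = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {len(classes)}")
    if np.any(counts < 2):
        small = classes[counts < 2][0]
        raise ValueError(f"class {small!r} has fewer than 2 members")
    if metric == "bray_curtis":
        X = minmax_rescale(X)
    M = _dissimilarity_matrix(X, metric)
    return M, labels == classes[0], {str(c): int(n) for c, n in zip(classes, counts)}


def _ratio_from_matrix(M: np.ndarray, b: np.ndarray) -> float:
    """Between/within mean-dissimilarity ratio for boolean partition b."""
    nb = int(b.sum())
    nw = len(b) - nb
    between = float(M[b][:, ~b].sum())
    within = float(M[b][:, b].sum() + M[~b][:, ~b].sum()) / 2.0
    n_between = nb * nw
    n_within = nb * (nb - 1) // 2 + nw * (nw - 1) // 2
    mean_between = between / n_between
    mean_within = within / n_within
    if mean_within == 0:
        return np.inf
    return mean_between / mean_within


def separation_score(profiles: np.ndarray, labels, metric: str = "bray_curtis") -> float:
    """D = mean between-class dissimilarity / mean within-class dissimilarity.

    Symmetric in the class labels; +inf (flagged by the caller) when the
    within mean is zero.
    """
    M, b, _ = _prepare(profiles, np.asarray(labels), metric)
    return _ratio_from_matrix(M, b)


def permutation_test(
    profiles: np.ndarray,
    labels,
    metric: str = "bray_curtis",
    n_perm: int = 999,
    seed: int = 0,
) -> SeparationResult:
    """Label-permutation test of the separation statistic.

    p = (1 + #{permuted D >= observed D}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError(f"n_perm must be >= 19, got {n_perm}")
    labels = np.asarray(labels)
    M, b, sizes = _prepare(profiles, labels, metric)
    observed = _ratio_from_matrix(M, b)
    rng = np.random.default_rng(seed)
    n = len(b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _ratio_from_matrix(M, b[perm]) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SeparationResult(
        metric=metric,
        statistic=float(observed) if np.isfinite(observed) else float("inf"),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        group_sizes=sizes,
        observed_infinite=not np.isfinite(observed),
    )


def cluster_view(
    profiles: np.ndarray, linkage_method: str = "ward"
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scaled matrix plus hierarchical-clustering leaf order.

    Each component is rescaled to [0, 1]; agglomerative clustering runs
    on Euclidean distances of the scaled profiles.
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 profiles to cluster")
    S = minmax_rescale(X)
    Z = linkage(S, method=linkage_method, metric="euclidean")
    order = leaves_list(Z)
    return order, S
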