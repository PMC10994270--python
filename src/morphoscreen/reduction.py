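"""Correlation-matrix PCA, component selection, oblimin rotation and
ten Berge factor scores.

The signature space is built by extracting k principal components from
the feature correlation matrix, obliquely rotating the retained loading
matrix toward simple structure (direct oblimin, gradient-projection
algorithm) and computing correlation-preserving factor scores: the
scores' sample correlation matrix equals the factor correlation matrix
Phi exactly, by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import feature_columns, metadata_columns


class RotationConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.criterion_trace = trace


# ---------------------------------------------------------------- helpers

def _sym_eig(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    return vals[::-1], vecs[:, ::-1]


def matrix_power_sym(M: np.ndarray, power: float, rcond: float = 1e-12) -> np.ndarray:
    """Fractional power of a symmetric PSD matrix via eigendecomposition."""
    vals, vecs = _sym_eig(M)
    cut = rcond * max(vals[0], 0.0)
    if power < 0 and np.any(vals <= cut):
        raise np.linalg.LinAlgError(
            "matrix is numerically rank-deficient; remove collinear features "
            "(drop_degenerate) before scoring"
        )
    safe = np.where(vals > cut, vals, np.inf if power < 0 else 0.0)
    return (vecs * safe**power) @ vecs.T


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|loading| entry of each column is positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return flip


# ---------------------------------------------------------------- PCA

@dataclass
class PCAModel:
    """Correlation-matrix PCA of a well-by-feature table."""

    feature_names: list[str]
    mean: np.ndarray           # training means
    std: np.ndarray            # training SDs (ddof=1)
    eigenvalues: np.ndarray    # all, non-increasing
    eigenvectors: np.ndarray   # columns, matching eigenvalues

    def loadings(self, k: int) -> np.ndarray:
        """Unrotated component loadings V_k * sqrt(lambda_k)."""
        lam = np.clip(self.eigenvalues[:k], 0.0, None)
        A = self.eigenvectors[:, :k] * np.sqrt(lam)
        return A * _fix_signs(A)

    def standardize(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        return (X - self.mean) / self.std

    def scores(self, table: pd.DataFrame, k: int) -> np.ndarray:
        """Raw principal-component scores Z V_k (variance lambda_j),
        signed to follow the loading sign convention."""
        lam = np.clip(self.eigenvalues[:k], 0.0, None)
        V = self.eigenvectors[:, :k] * _fix_signs(self.eigenvectors[:, :k] * np.sqrt(lam))
        return self.standardize(table) @ V


def fit_pca(table: pd.DataFrame) -> PCAModel:
    """Eigendecomposition of the feature correlation matrix.

    Features are standardized with the training mean/SD; the sum of the
    eigenvalues equals the number of features (trace of the correlation
    matrix).
    """
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 wells to fit a PCA")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature table")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [f for f, s in zip(feats, std) if s == 0]
        raise ValueError(f"constant features (run drop_degenerate first): {bad[:5]}")
    Z = (X - mean) / std
    R = (Z.T @ Z) / (X.shape[0] - 1)
    vals, vecs = _sym_eig(R)
    return PCAModel(
        feature_names=feats,
        mean=mean,
        std=std,
        eigenvalues=np.clip(vals, 0.0, None),
        eigenvectors=vecs,
    )


def select_components(eigenvalues: np.ndarray, rule: str = "fixed", k0: int = 50) -> int:
    """Number of components to retain.

    kaiser: count of eigenvalues strictly greater than 1.
    scree:  elbow by maximum second difference of the sorted eigenvalues.
    fixed:  k0, capped at the number of available components.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    if rule == "kaiser":
        return int(np.sum(lam > 1.0))
    if rule == "scree":
        if lam.size < 3:
            return lam.size
        d2 = lam[:-2] - 2 * lam[1:-1] + lam[2:]
        return int(np.argmax(d2)) + 1  # elbow position, 1-based
    if rule == "fixed":
        return int(min(k0, lam.size))
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------- oblimin

def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Direct-oblimin criterion and its gradient wrt the loadings.

    Uses L2 @ (ones - I) = rowsum(L2) - L2, so the cost is O(p*k).
    """
    p = L.shape[0]
    L2 = L**2
    X = L2.sum(axis=1, keepdims=True) - L2
    if gamma != 0.0:
        X = X - (gamma / p) * X.sum(axis=0, keepdims=True)
    f = float(np.sum(L2 * X)) / 4.0
    G = L * X
    return f, G


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 10000,
    grad_tol: float = 1e-6,
    n_starts: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oblique rotation minimizing the direct-oblimin criterion.

    Gradient-projection algorithm over oblique rotation matrices T with
    unit-length columns; gamma=0 gives direct quartimin.  Convergence is
    declared when the projected gradient norm falls below ``grad_tol``
    (the criterion itself then changes by far less than the gradient
    norm per step).  With ``n_starts > 1`` additional random orthonormal
    starts are tried and the lowest-criterion solution kept.

    Returns (rotated pattern Lambda, rotation T, factor correlation Phi),
    with Lambda = A @ inv(T).T and Phi = T.T @ T, columns sign-fixed so
    the largest-|loading| entry is positive.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("loadings must be n_features x k with k >= 2")
    k = A.shape[1]
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray] | None = None
    last_trace: list[float] = []
    for start in range(max(n_starts, 1)):
        if start == 0:
            T = np.eye(k)
        else:
            Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
            T = Q
        f, T, trace, converged = _gpa_oblique(A, T, gamma, min(max_iter, 500), grad_tol)
        if not converged:
            # quasi-Newton polish on the normalized-column parameterization;
            # escapes the long shallow plateaus where plain GPA crawls
            f, T, s = _lbfgs_polish(A, T, gamma, grad_tol, max_iter)
            trace.append(f)
            converged = s < max(grad_tol, 1e-4 * max(1.0, abs(f)))
        last_trace = trace
        if converged and (best is None or f < best[0]):
            best = (f, T)
    if best is None:
        raise RotationConvergenceError(
            f"oblimin failed to converge in {max_iter} iterations", last_trace
        )
    T = best[1]
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    signs = _fix_signs(L)
    L = L * signs
    T = T * signs  # flipping a factor's sign flips its column of T
    Phi = T.T @ T
    return L, T, Phi


def _gpa_oblique(
    A: np.ndarray, T: np.ndarray, gamma: float, max_iter: int, grad_tol: float
) -> tuple[float, np.ndarray, list[float], bool]:
    """One gradient-projection run (Bernaards & Jennrich style)."""
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    trace = [f]
    converged = False
    stalled = 0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)  # project onto the constraint manifold
        s = np.linalg.norm(Gp)
        if s < grad_tol:
            converged = True
            break
        al *= 2.0
        f_new, T_new, L_new = f, T, L
        improved = False
        for _ in range(60):
            X = T - al * Gp
            nv = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            T_new = X * nv
            Ti_new = np.linalg.inv(T_new)
            L_new = A @ Ti_new.T
            f_new, Gq = _oblimin_criterion(L_new, gamma)
            if f_new < f - 0.5 * s**2 * al:
                improved = True
                break
            al /= 2.0
        df = f - f_new
        T, L, f = T_new, L_new, f_new
        Ti = np.linalg.inv(T)
        G = -(L.T @ Gq @ Ti).T
        trace.append(f)
        # numerical floor: descent exhausted in double precision
        stalled = stalled + 1 if (not improved or df < 1e-16) else 0
        if stalled >= 5:
            converged = s < 1e-3
            break
    return f, T, trace, converged


def _lbfgs_polish(
    A: np.ndarray, T0: np.ndarray, gamma: float, grad_tol: float, max_iter: int
) -> tuple[float, np.ndarray, float]:
    """Minimize the criterion over T = X / ||X||_col by L-BFGS.

    Returns (criterion, T, projected-gradient norm at the solution).
    """
    from scipy.optimize import minimize

    k = T0.shape[1]

    def fg(x: np.ndarray) -> tuple[float, np.ndarray]:
        X = x.reshape(k, k)
        nrm = np.sqrt(np.sum(X**2, axis=0))
        T = X / nrm
        Ti = np.linalg.inv(T)
        L = A @ Ti.T
        f, Gq = _oblimin_criterion(L, gamma)
        G = -(L.T @ Gq @ Ti).T
        GX = (G - T * np.sum(T * G, axis=0)) / nrm
        return f, GX.ravel()

    res = minimize(
        fg, T0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": grad_tol / 10, "maxcor": 20},
    )
    X = res.x.reshape(k, k)
    T = X / np.sqrt(np.sum(X**2, axis=0))
    f, s_vec = fg(res.x)
    return f, T, float(np.linalg.norm(s_vec))


# ---------------------------------------------------------------- ten Berge

def tenberge_weights(R: np.ndarray, Lambda: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Weight matrix W of the correlation-preserving factor scores.

    For standardized data Z with correlation matrix R, scores F = Z W
    satisfy corr(F) = Phi exactly:

        Lt = Lambda Phi^{1/2}
        C  = R^{-1/2} Lt (Lt' R^{-1} Lt)^{-1/2}
        W  = R^{-1/2} C Phi^{1/2}
    """
    Phi_h = matrix_power_sym(Phi, 0.5)
    R_ih = matrix_power_sym(R, -0.5)
    R_i = R_ih @ R_ih
    Lt = Lambda @ Phi_h
    M = matrix_power_sym(Lt.T @ R_i @ Lt, -0.5)
    C = R_ih @ Lt @ M
    return R_ih @ C @ Phi_h


def tenberge_scores(Z: np.ndarray, Lambda: np.ndarray, Phi: np.ndarray,
                    R: np.ndarray | None = None) -> np.ndarray:
    """Correlation-preserving factor scores of standardized data Z.

    The scores have unit variance and sample correlation matrix exactly
    Phi (to numerical precision) when R is the sample correlation of Z.
    """
    Z = np.asarray(Z, dtype=float)
    if R is None:
        R = (Z.T @ Z) / (Z.shape[0] - 1)
    if Lambda.shape[0] != Z.shape[1] or Lambda.shape[1] != Phi.shape[0]:
        raise ValueError("dimension mismatch between data, loadings and Phi")
    return Z @ tenberge_weights(R, Lambda, Phi)


# ---------------------------------------------------------------- model

@dataclass
class ReductionModel:
    """Fitted signature-space model: PCA + optional oblimin + ten Berge."""

    pca: PCAModel
    k: int
    selection_rule: str
    rotate: bool
    gamma: float
    loadings: np.ndarray          # rotated pattern (or unrotated A)
    rotation: np.ndarray          # T (identity if unrotated)
    phi: np.ndarray               # factor correlation (identity if unrotated)
    score_weights: np.ndarray     # W: standardized data -> scores

    @property
    def score_names(self) -> list[str]:
        return [f"PC{j + 1:02d}" for j in range(self.k)]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Score wells/images with the training standardization and weights."""
        Z = self.pca.standardize(table)
        F = Z @ self.score_weights
        meta = table[metadata_columns(table)].reset_index(drop=True)
        return pd.concat([meta, pd.DataFrame(F, columns=self.score_names)], axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.pca.feature_names,
            "mean": self.pca.mean.tolist(),
            "std": self.pca.std.tolist(),
            "eigenvalues": self.pca.eigenvalues.tolist(),
            "k": self.k,
            "selection_rule": self.selection_rule,
            "rotate": self.rotate,
            "gamma": self.gamma,
            "loadings": self.loadings.tolist(),
            "rotation": self.rotation.tolist(),
            "phi": self.phi.tolist(),
            "score_weights": self.score_weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_reduction(
    table: pd.DataFrame,
    rule: str = "fixed",
    k0: int = 50,
    rotate: bool = True,
    gamma: float = 0.0,
    seed: int = 0,
) -> ReductionModel:
    """Fit the full signature-space model on a well-level table.

    With ``rotate=False`` the scores are standardized principal-component
    scores (weights V_k / sqrt(lambda) give unit variance... here raw PC
    scores are kept as Z V_k so the unrotated mode matches ordinary PCA).
    """
    pca = fit_pca(table)
    k = select_components(pca.eigenvalues, rule=rule, k0=k0)
    if k < 1:
        raise ValueError(f"selection rule {rule!r} retained no components")
    A = pca.loadings(k)
    Z = pca.standardize(table)
    R = (Z.T @ Z) / (Z.shape[0] - 1)
    if rotate and k >= 2:
        L, T, Phi = oblimin_rotate(A, gamma=gamma, seed=seed)
        W = tenberge_weights(R, L, Phi)
    else:
        L, T, Phi = A, np.eye(k), np.eye(k)
        V = pca.eigenvectors[:, :k]
        W = V * _fix_signs(V * np.sqrt(np.clip(pca.eigenvalues[:k], 0.0, None)))
    return ReductionModel(
        pca=pca, k=k, selection_rule=rule, rotate=rotate and k >= 2, gamma=gamma,
        loadings=L, rotation=T, phi=Phi, score_weights=W,
    )
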