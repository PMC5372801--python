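"""Partial least squares regression with permutation inference and VIP scores.

The model is the two-block decomposition

    X = T P' + E ,    Y = U Q' + F ,

extracted one latent variable at a time: each weight vector w (unit norm)
maximises the covariance between the X-score t = X w and the Y block, which
for a single dependent variable is achieved in closed form by w ∝ X'y — the
left singular vector of the cross-covariance matrix X'Y.  Loadings are
obtained by regressing the blocks on t, and both blocks are deflated
(NIPALS with Y-deflation).  The residual F is defined through the X-scores
(the regression form Y = T Q' + F, exact by construction); the Y-block
scores U are retained as diagnostics of the inner relation.

Significance of each latent variable is assessed by permuting the rows of Y
and recomputing the cross-covariance singular value; variable selection uses
Wold's Variable Importance in the Projection (VIP), whose squares average to
one so that the conventional ">1" rule applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "PermutationResult",
    "VIPScores",
    "fit_pls",
    "explained_variance",
    "permutation_test",
    "vip_scores",
    "select_latent_variables",
    "impute_features",
]

_EPS = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS decomposition (predictors X, dependent block Y)."""

    n: int
    p: int
    q: int
    r: int
    weights: np.ndarray            # W, (p, r), unit-norm columns
    x_scores: np.ndarray           # T, (n, r)
    y_scores: np.ndarray           # U, (n, r), inner-relation diagnostics
    x_loadings: np.ndarray         # P, (p, r)
    y_loadings: np.ndarray         # Q, (q, r)
    singular_values: np.ndarray    # (r,) cross-covariance singular values
    explained_x: np.ndarray        # (r,) fraction of centred SS of X per component
    explained_y: np.ndarray        # (r,)
    x_residual: np.ndarray         # E, (n, p)
    y_residual: np.ndarray         # F, (n, q)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    scaled: bool


@dataclass
class PermutationResult:
    """Permutation null for one latent variable's singular value."""

    component: int
    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    null_values: np.ndarray = field(repr=False, default=None)


@dataclass
class VIPScores:
    """Wold's VIP per predictor; mean of squares equals 1 by construction."""

    vip: np.ndarray
    selected: np.ndarray            # indices with VIP > 1
    columns: list[str] | None = None

    def selected_columns(self) -> list[str]:
        if self.columns is None:
            return [str(i) for i in self.selected]
        return [self.columns[i] for i in self.selected]


def _prepare(X, Y, scale: bool):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X must be (n, p) and Y (n, q) with matching n")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("X/Y contain missing values; impute upstream (impute_features)")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale < _EPS] = 1.0
        Xc = Xc / x_scale
    else:
        x_scale = np.ones(X.shape[1])
    return Xc, Yc, x_mean, x_scale, y_mean


def fit_pls(X, Y, n_components: int = 1, scale: bool = True) -> PLSModel:
    """Fit a PLS decomposition with ``n_components`` latent variables.

    Predictor columns are centred and (by default) standardised with the
    sample SD; Y is centred.  The sign of each weight vector is fixed so
    that its largest-magnitude element is positive, making loadings stable
    across runs.

    Raises on missing values, constant Y, or ``n_components`` exceeding
    min(n - 1, p).
    """
    Xc, Yc, x_mean, x_scale, y_mean = _prepare(X, Y, scale)
    n, p = Xc.shape
    q = Yc.shape[1]
    if n < 3:
        raise ValueError("need at least 3 observations")
    tss_y = float((Yc ** 2).sum())
    if tss_y < _EPS:
        raise ValueError("Y has zero variance")
    r = int(n_components)
    if r < 1 or r > min(n - 1, p):
        raise ValueError(f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    tss_x = float((Xc ** 2).sum())

    W = np.zeros((p, r))
    T = np.zeros((n, r))
    U = np.zeros((n, r))
    P = np.zeros((p, r))
    Q = np.zeros((q, r))
    sv = np.zeros(r)
    exp_x = np.zeros(r)
    exp_y = np.zeros(r)

    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(r):
        C = Xd.T @ Yd                       # (p, q) cross-covariance (unnormalised)
        if q == 1:
            s = float(np.linalg.norm(C))
            if s < _EPS:                    # Y orthogonal to every predictor
                break
            w = C[:, 0] / s
            c = np.ones(1)
        else:
            Uc, Sc, Vc = np.linalg.svd(C, full_matrices=False)
            s = float(Sc[0])
            if s < _EPS:
                break
            w, c = Uc[:, 0], Vc[0]
        # sign convention: largest-|.| weight element positive
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w, c = -w, -c
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p_a = Xd.T @ t / tt
        q_a = Yd.T @ t / tt
        u = Yd @ c
        Xd = Xd - np.outer(t, p_a)
        Yd = Yd - np.outer(t, q_a)
        W[:, a], T[:, a], U[:, a], P[:, a], Q[:, a], sv[a] = w, t, u, p_a, q_a, s
        exp_x[a] = tt * float(p_a @ p_a) / tss_x if tss_x > 0 else 0.0
        exp_y[a] = tt * float(q_a @ q_a) / tss_y

    return PLSModel(
        n=n, p=p, q=q, r=r,
        weights=W, x_scores=T, y_scores=U, x_loadings=P, y_loadings=Q,
        singular_values=sv, explained_x=exp_x, explained_y=exp_y,
        x_residual=Xd, y_residual=Yd,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, scaled=scale,
    )


def explained_variance(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component fractions of the centred sum of squares of X and Y."""
    return model.explained_x.copy(), model.explained_y.copy()


def _component_singular_value(Xc: np.ndarray, Yc: np.ndarray, component: int) -> float:
    """Cross-covariance singular value of the given component (1-based)."""
    Xd, Yd = Xc, Yc
    for _ in range(component - 1):
        C = Xd.T @ Yd
        if Yd.shape[1] == 1:
            s = float(np.linalg.norm(C))
            if s < _EPS:
                return 0.0
            w = C[:, 0] / s
        else:
            Uc, Sc, _ = np.linalg.svd(C, full_matrices=False)
            s = float(Sc[0])
            if s < _EPS:
                return 0.0
            w = Uc[:, 0]
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            return 0.0
        Xd = Xd - np.outer(t, Xd.T @ t / tt)
        Yd = Yd - np.outer(t, Yd.T @ t / tt)
    C = Xd.T @ Yd
    if Yd.shape[1] == 1:
        return float(np.linalg.norm(C))
    return float(np.linalg.svd(C, compute_uv=False)[0])


def permutation_test(
    X,
    Y,
    component: int = 1,
    n_permutations: int = 5000,
    seed: int | np.random.Generator | None = None,
    scale: bool = True,
) -> PermutationResult:
    """Permutation test on a latent variable's cross-covariance singular value.

    The rows of Y are permuted uniformly at random ``n_permutations`` times
    and the singular value of the requested component is recomputed each
    time; the p-value uses the add-one Monte-Carlo estimator

        p = (1 + #{null >= observed}) / (n_permutations + 1),

    so p is never zero and attains 1/(B+1) when the observed value exceeds
    the whole null sample.  A constant Y yields p = 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if component < 1:
        raise ValueError("component is 1-based and must be >= 1")
    Xc, Yc, *_ = _prepare(X, Y, scale)
    n = Xc.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _component_singular_value(Xc, Yc, component)

    B = int(n_permutations)
    if component == 1 and Yc.shape[1] == 1:
        # vectorised: all permuted Y columns at once (centring is permutation
        # invariant, so Yc can be permuted directly)
        perms = np.empty((n, B))
        y = Yc[:, 0]
        for b in range(B):
            perms[:, b] = y[rng.permutation(n)]
        null = np.linalg.norm(Xc.T @ perms, axis=0)
    else:
        null = np.empty(B)
        for b in range(B):
            Yp = Yc[rng.permutation(n)]
            null[b] = _component_singular_value(Xc, Yp, component)
    p = (1.0 + int((null >= observed - _EPS).sum())) / (B + 1.0)
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationResult(component=component, observed=observed,
                             n_permutations=B, p_value=float(p),
                             seed=seed_out, null_values=null)


def vip_scores(model: PLSModel, n_components: int | None = None,
               columns: list[str] | None = None) -> VIPScores:
    """Wold's Variable Importance in the Projection over the first components.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ), with SSY_a the
    Y-variance explained by component a and w the unit-norm weights.  The
    mean of the squared VIPs over the p predictors equals 1, so predictors
    with VIP > 1 are flagged as important.
    """
    a = model.r if n_components is None else int(n_components)
    if a < 1 or a > model.r:
        raise ValueError(f"n_components must lie in [1, {model.r}]")
    ssy = model.explained_y[:a]
    total = float(ssy.sum())
    if total < _EPS:
        raise ValueError("model explains no Y variance; VIP undefined")
    w2 = model.weights[:, :a] ** 2
    vip = np.sqrt(model.p * (w2 @ ssy) / total)
    selected = np.flatnonzero(vip > 1.0)
    return VIPScores(vip=vip, selected=selected, columns=columns)


def select_latent_variables(
    explained_y: np.ndarray,
    p_values: np.ndarray,
    alpha: float = 0.05,
    y_variance_threshold: float = 0.05,
) -> int:
    """Number of leading latent variables to retain.

    Components are scanned in order; a component is retained while its
    permutation p-value is below ``alpha`` AND it explains at least
    ``y_variance_threshold`` of the dependent variable's variance.  The scan
    stops at the first failure.
    """
    explained_y = np.asarray(explained_y, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if explained_y.shape != p_values.shape:
        raise ValueError("explained_y and p_values must align")
    retained = 0
    for ev, p in zip(explained_y, p_values):
        if p < alpha and ev >= y_variance_threshold:
            retained += 1
        else:
            break
    return retained


def impute_features(features: pd.DataFrame, strategy: str = "mean") -> pd.DataFrame:
    """Resolve missing feature cells (empty compartments) before PLS.

    ``mean`` replaces each missing cell by its column mean over patients;
    ``drop`` removes patients with any missing cell.
    """
    if strategy == "mean":
        out = features.fillna(features.mean(axis=0))
        if out.isna().any().any():
            raise ValueError("a feature column is entirely missing; cannot impute")
        return out
    if strategy == "drop":
        return features.dropna(axis=0)
    raise ValueError("strategy must be 'mean' or 'drop'")
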