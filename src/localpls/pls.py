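"""Single-response partial least squares regression (PLS1).

The regression core works on the centred cross-product moments ``X'X`` and
``X'y`` (the kernel form of the orthogonal-scores PLS algorithm, after
Dayal & MacGregor).  This form is algebraically identical to NIPALS for a
single response but makes leave-one-out work cheap: removing a sample is a
rank-one downdate of the moments, so all LOO folds can be processed as one
batched recursion instead of ``n`` separate fits.

X is centred but never scaled inside the regression; when spectral
standardisation is requested it applies to the neighbour-selection geometry
upstream, not to the regression itself.  The number of factors is selected
by leave-one-out cross-validation with ties broken toward parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "predict",
    "select_factors_loocv",
    "loo_global_benchmark",
]

_DEFAULT_CHUNK = 64


@dataclass
class PLSModel:
    """A fitted PLS1 model mapping centred spectra to a centred response."""

    x_center: np.ndarray
    y_center: float
    n_factors: int
    coefficients: np.ndarray
    x_scale: np.ndarray | None = None
    training_ids: np.ndarray | None = field(default=None, repr=False)


@dataclass
class CVResult:
    """Leave-one-out RMSECV per factor count and the chosen count."""

    rmsecv_by_factors: np.ndarray
    chosen_factors: int


def _coef_paths(S: np.ndarray, s: np.ndarray, n_factors: int):
    """Batched PLS1 coefficient paths from centred moments.

    Parameters
    ----------
    S : (F, p, p) centred cross-products ``Xc' Xc`` per problem.
    s : (F, p) centred cross-covariances ``Xc' yc`` per problem.
    n_factors : number of latent factors to extract.

    Returns
    -------
    B : (F, p, n_factors) regression coefficients for 1..n_factors factors.
    n_effective : (F,) number of factors actually extracted before the
        residual cross-covariance vanished (rank exhaustion); coefficient
        columns beyond it repeat the last valid ones.
    """
    S = np.asarray(S, dtype=float)
    s_def = np.array(s, dtype=float, copy=True)
    if S.ndim == 2:
        S = S[None]
        s_def = s_def[None]
    F, p = s_def.shape
    A = n_factors
    # The cross-product matrix is never deflated; only the cross-covariance
    # is.  The orthogonalised weights r_a (columns of W (P'W)^{-1}) are
    # built incrementally, so coefficients accumulate as B_a = B_{a-1} +
    # r_a q_a and scores refer to the undeflated predictors throughout.
    P = np.zeros((F, p, A))
    R = np.zeros((F, p, A))
    B = np.zeros((F, p, A))
    s0 = np.linalg.norm(s_def, axis=1)
    t0 = np.einsum("fii->f", S)
    n_eff = np.zeros(F, dtype=int)
    b_prev = np.zeros((F, p))
    for a in range(A):
        nrm = np.linalg.norm(s_def, axis=1)
        active = nrm > 1e-12 * np.maximum(s0, 1e-300)
        w = s_def / np.where(nrm > 0, nrm, 1.0)[:, None]
        if a > 0:
            coef = np.einsum("fpb,fp->fb", P[:, :, :a], w)
            r = w - np.einsum("fpb,fb->fp", R[:, :, :a], coef)
        else:
            r = w
        Sr = np.einsum("fij,fj->fi", S, r)
        tt = np.einsum("fi,fi->f", r, Sr)
        active &= tt > 1e-14 * np.maximum(t0, 1e-300)
        tt_safe = np.where(active, tt, 1.0)
        pv = Sr / tt_safe[:, None]
        pv[~active] = 0.0
        q = np.einsum("fi,fi->f", r, s_def) / tt_safe
        q[~active] = 0.0
        r = np.where(active[:, None], r, 0.0)
        s_def -= (q * tt_safe)[:, None] * pv
        P[:, :, a] = pv
        R[:, :, a] = r
        b_prev = b_prev + r * q[:, None]
        B[:, :, a] = b_prev
        n_eff += active
    return B, n_eff


def _moments(X: np.ndarray, y: np.ndarray):
    Xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - Xm
    return Xm, ym, Xc.T @ Xc, Xc.T @ (y - ym)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    training_ids=None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_factors`` latent factors.

    With ``n_factors`` equal to the rank of the centred predictors the fit
    coincides with the least-squares solution.  Requesting more factors
    than the data's rank raises an error naming the rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different sample counts")
    if n_factors < 1:
        raise ValueError("n_factors must be positive")
    if n < n_factors + 1:
        raise ValueError(f"need at least {n_factors + 1} samples for {n_factors} factors")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    Xm, ym, S, s = _moments(X, y)
    B, n_eff = _coef_paths(S, s, n_factors)
    if n_eff[0] < n_factors:
        raise ValueError(
            f"requested {n_factors} factors but the effective rank of the "
            f"training data is {int(n_eff[0])}"
        )
    return PLSModel(
        x_center=Xm,
        y_center=ym,
        n_factors=n_factors,
        coefficients=B[0, :, n_factors - 1],
        training_ids=None if training_ids is None else np.asarray(training_ids),
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """``yhat = y_center + (x - x_center) @ coefficients`` (row-wise)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.x_center):
        raise ValueError(
            f"expected {len(model.x_center)} wavelengths, got {X_new.shape[1]}"
        )
    Xc = X_new - model.x_center
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    return model.y_center + Xc @ model.coefficients


def select_factors_loocv(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    chunk: int = _DEFAULT_CHUNK,
) -> CVResult:
    """Choose the factor count by exact leave-one-out cross-validation.

    ``RMSECV(a) = sqrt(mean_i (y_i - yhat_{-i,a})^2)`` for ``a`` from 1 to
    ``max_factors``; the chosen count is the argmin, ties to the smallest
    ``a``.  Every fold is an exact refit (via rank-one moment downdates).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    if max_factors < 1 or max_factors > min(n - 2, p):
        raise ValueError(
            f"max_factors must be in [1, {min(n - 2, p)}] for n={n}, p={p}"
        )
    A = max_factors
    Xm = X.mean(axis=0)
    Xc = X - Xm
    ym = y.mean()
    yc = y - ym
    Sxx = Xc.T @ Xc
    Sxy = Xc.T @ yc
    sx = Xc.sum(axis=0)
    sy = yc.sum()
    errs = np.empty((n, A))
    m = n - 1
    for lo in range(0, n, chunk):
        idx = np.arange(lo, min(lo + chunk, n))
        xi = Xc[idx]
        yi = yc[idx]
        sxf = sx[None, :] - xi
        syf = sy - yi
        Sf = (
            Sxx[None]
            - xi[:, :, None] * xi[:, None, :]
            - sxf[:, :, None] * sxf[:, None, :] / m
        )
        sf = Sxy[None, :] - xi * yi[:, None] - sxf * (syf / m)[:, None]
        B, _ = _coef_paths(Sf, sf, A)
        dx = xi - sxf / m
        pred = (syf / m)[:, None] + np.einsum("fp,fpa->fa", dx, B)
        errs[idx] = yi[:, None] - pred
    rmsecv = np.sqrt(np.mean(errs**2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # first minimum -> fewest factors
    return CVResult(rmsecv_by_factors=rmsecv, chosen_factors=chosen)


def loo_global_benchmark(
    X: np.ndarray,
    Y: np.ndarray,
    max_factors: int = 20,
    chunk: int = _DEFAULT_CHUNK,
):
    """Leave-one-out global-PLSR predictions for every sample and trait.

    For each predictand ``j`` and trait ``t`` this reproduces exactly the
    per-predictand procedure: the factor count is chosen by leave-one-out
    cross-validation *within* the remaining ``n-1`` samples, then a model
    with that count is fitted on those samples and applied to ``j``.  The
    inner folds for different predictands share their pair-deleted fits
    (the fit excluding ``{i, j}`` serves predictand ``j`` at fold ``i`` and
    predictand ``i`` at fold ``j``), which this routine exploits.

    Returns
    -------
    yhat : (n, T) predictions.
    factors : (n, T) chosen factor counts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    T = Y.shape[1]
    A = max_factors
    if A < 1 or A > min(n - 3, p):
        raise ValueError(f"max_factors must be in [1, {min(n - 3, p)}] for n={n}, p={p}")
    Xm = X.mean(axis=0)
    Xc = X - Xm
    Ym = Y.mean(axis=0)
    Yc = Y - Ym
    Sxx = Xc.T @ Xc
    Sxy = Xc.T @ Yc
    sx = Xc.sum(axis=0)
    sy = Yc.sum(axis=0)
    # E[i, j, a, t]: error predicting sample i from the fit excluding {i, j}
    # with a+1 factors.
    E = np.full((n, n, A, T), np.nan)
    m2 = n - 2
    for j in range(n - 1):
        xj = Xc[j]
        yj = Yc[j]
        Sxx_j = Sxx - np.outer(xj, xj)
        Sxy_j = Sxy - xj[:, None] * yj[None, :]
        sx_j = sx - xj
        sy_j = sy - yj
        others = np.arange(j + 1, n)
        for lo in range(0, len(others), chunk):
            idx = others[lo : lo + chunk]
            xi = Xc[idx]
            yi = Yc[idx]
            sxf = sx_j[None, :] - xi
            xbar = sxf / m2
            Sf = (
                Sxx_j[None]
                - xi[:, :, None] * xi[:, None, :]
                - sxf[:, :, None] * sxf[:, None, :] / m2
            )
            dxi = xi - xbar
            dxj = xj[None, :] - xbar
            for t in range(T):
                syf = sy_j[t] - yi[:, t]
                sf = Sxy_j[None, :, t] - xi * yi[:, t][:, None] - sxf * (syf / m2)[:, None]
                B, _ = _coef_paths(Sf, sf, A)
                ybar = (syf / m2)[:, None]
                E[idx, j, :, t] = yi[:, t][:, None] - (
                    ybar + np.einsum("fp,fpa->fa", dxi, B)
                )
                E[j, idx, :, t] = yj[t] - (ybar + np.einsum("fp,fpa->fa", dxj, B))
    # Per-predictand factor choice from its own inner-CV error column.
    mask = ~np.eye(n, dtype=bool)
    factors = np.empty((n, T), dtype=int)
    for t in range(T):
        for j in range(n):
            rmsecv = np.sqrt(np.mean(E[mask[:, j], j, :, t] ** 2, axis=0))
            factors[j, t] = int(np.argmin(rmsecv)) + 1
    # Final fits on the n-1 remaining samples, batched over predictands.
    yhat = np.empty((n, T))
    m1 = n - 1
    for lo in range(0, n, chunk):
        idx = np.arange(lo, min(lo + chunk, n))
        xi = Xc[idx]
        yi = Yc[idx]
        sxf = sx[None, :] - xi
        Sf = (
            Sxx[None]
            - xi[:, :, None] * xi[:, None, :]
            - sxf[:, :, None] * sxf[:, None, :] / m1
        )
        dxi = xi - sxf / m1
        for t in range(T):
            syf = sy[t] - yi[:, t]
            sf = Sxy[None, :, t] - xi * yi[:, t][:, None] - sxf * (syf / m1)[:, None]
            B, _ = _coef_paths(Sf, sf, A)
            preds = (syf / m1)[:, None] + np.einsum("fp,fpa->fa", dxi, B)
            yhat[idx, t] = preds[np.arange(len(idx)), factors[idx, t] - 1]
    return yhat + Ym, factors


def save_model(model: PLSModel, path) -> None:
    """Serialise a PLS model to plain text for audit."""
    with open(path, "w") as fh:
        fh.write(f"n_factors {model.n_factors}\n")
        fh.write(f"y_center {model.y_center!r}\n")
        fh.write("x_center " + " ".join(repr(float(v)) for v in model.x_center) + "\n")
        fh.write(
            "coefficients "
            + " ".join(repr(float(v)) for v in model.coefficients)
            + "\n"
        )
        if model.training_ids is not None:
            fh.write("training_ids " + " ".join(str(i) for i in model.training_ids) + "\n")


def load_model(path) -> PLSModel:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, rest = line.rstrip("\n").split(" ", 1)
            fields[key] = rest
    return PLSModel(
        x_center=np.array([float(v) for v in fields["x_center"].split()]),
        y_center=float(fields["y_center"]),
        n_factors=int(fields["n_factors"]),
        coefficients=np.array([float(v) for v in fields["coefficients"].split()]),
        training_ids=(
            np.array(fields["training_ids"].split(), dtype=object)
            if "training_ids" in fields
            else None
        ),
    )
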