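"""Principal-component geometry for spectral similarity.

Neighbour selection operates in the space of the leading principal
components of the (optionally standardised) absorbance matrix.  Because PC
scores are uncorrelated, the Mahalanobis distance between two samples in
that space reduces to a Euclidean distance weighted by the reciprocal
component variances (the eigenvalues of the covariance of the fitting set).

Four components are used by default: for milk mid-infrared spectra they
carry essentially all spectral variability (>98% standardised, >99.9%
unstandardised), and adding more does not change which neighbours are
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCSpace",
    "fit_pc_space",
    "project",
    "mahalanobis",
    "center_distances",
    "save_pc_space",
    "load_pc_space",
]

# Relative eigenvalue threshold below which a component is considered to lie
# outside the numerical rank of the data.
_RANK_RTOL = 1e-10


@dataclass
class PCSpace:
    """Fitted principal-component geometry.

    Attributes
    ----------
    center : (p,) per-wavelength mean of the fitting spectra.
    scale : (p,) per-wavelength standard deviation (all ones when the space
        was fitted without standardisation).
    loadings : (p, k) orthonormal loading columns.
    component_variances : (k,) eigenvalues (variance of each score column,
        n-1 denominator), non-increasing.
    explained_share : (k,) fraction of total variance per component.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    component_variances: np.ndarray
    explained_share: np.ndarray
    standardised: bool

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_wavelengths(self) -> int:
        return self.loadings.shape[0]


def fit_pc_space(
    spectra: np.ndarray,
    standardise: bool = True,
    n_components: int = 4,
    on_deficient_rank: str = "error",
) -> PCSpace:
    """Fit the PC geometry of a spectral matrix.

    Parameters
    ----------
    spectra : (n, p) absorbance matrix.
    standardise : centre *and* scale each wavelength before the
        decomposition; otherwise centre only.
    n_components : number of leading components to retain.
    on_deficient_rank : "error" raises when the data have fewer than
        ``n_components`` non-negligible eigenvalues; "truncate" keeps the
        numerical rank instead.

    The loading sign convention is deterministic: the largest-magnitude
    entry of each column is made positive.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix")
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be positive")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, "
            f"n_wavelengths)={min(n - 1, p)}"
        )
    center = X.mean(axis=0)
    if standardise:
        scale = X.std(axis=0, ddof=1)
        zero = scale <= 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance wavelength(s); their scale "
                "is set to 1 for standardisation",
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
    else:
        scale = np.ones(p)
    Z = (X - center) / scale
    # SVD of the centred/scaled matrix: loadings are right singular vectors,
    # eigenvalues of the covariance are s^2/(n-1).
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    rank = int(np.sum(eigvals > _RANK_RTOL * eigvals[0])) if eigvals[0] > 0 else 0
    k = n_components
    if rank < n_components:
        if on_deficient_rank == "truncate":
            k = rank
        else:
            raise ValueError(
                f"requested {n_components} components but the numerical rank "
                f"of the data is {rank}"
            )
    loadings = Vt[:k].T.copy()
    # Deterministic sign: largest-|.| entry of each loading column positive.
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip = np.where(flip == 0, 1.0, flip)
    loadings *= flip
    total_var = Z.var(axis=0, ddof=1).sum()
    share = eigvals[:k] / total_var if total_var > 0 else np.zeros(k)
    return PCSpace(
        center=center,
        scale=scale,
        loadings=loadings,
        component_variances=eigvals[:k].copy(),
        explained_share=share,
        standardised=bool(standardise),
    )


def project(space: PCSpace, spectra: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted components, returning scores.

    ``scores = ((x - center) / scale) @ loadings``; projecting the fitting
    data reproduces the fitted scores.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != space.n_wavelengths:
        raise ValueError(
            f"spectra have {X.shape[1]} wavelengths, PC space expects "
            f"{space.n_wavelengths}"
        )
    return ((X - space.center) / space.scale) @ space.loadings


def mahalanobis(space: PCSpace, score_a: np.ndarray, score_b: np.ndarray) -> np.ndarray:
    """Mahalanobis distance between score vectors.

    PC scores of the fitting set are uncorrelated with variances equal to
    the eigenvalues, so the score covariance is diagonal and the distance is
    ``sqrt(sum_k (a_k - b_k)^2 / lambda_k)``.  Broadcasts over leading axes.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape[-1] != space.n_components or b.shape[-1] != space.n_components:
        raise ValueError("score dimension does not match the number of components")
    var = space.component_variances
    if np.any(var <= 0):
        raise ValueError("component variances must be positive")
    d2 = ((a - b) ** 2 / var).sum(axis=-1)
    return np.sqrt(d2)


def center_distances(space: PCSpace, scores: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each score row from the PC-space centre.

    The centre of the fitted space is the zero score vector (scores are
    computed about the fitting mean).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return mahalanobis(space, scores, np.zeros(space.n_components))


def save_pc_space(space: PCSpace, path) -> None:
    """Serialise a PC space to a plain-text file (for provenance/audit)."""
    with open(path, "w") as fh:
        fh.write(f"n_components {space.n_components}\n")
        fh.write(f"n_wavelengths {space.n_wavelengths}\n")
        fh.write(f"standardised {int(space.standardised)}\n")
        for name, arr in (
            ("center", space.center),
            ("scale", space.scale),
            ("component_variances", space.component_variances),
            ("explained_share", space.explained_share),
        ):
            fh.write(name + " " + " ".join(repr(float(v)) for v in arr) + "\n")
        fh.write("loadings\n")
        for row in space.loadings:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_pc_space(path) -> PCSpace:
    with open(path) as fh:
        lines = fh.read().splitlines()
    head = dict(line.split(" ", 1) for line in lines[:3])
    vectors = {}
    for line in lines[3:7]:
        name, rest = line.split(" ", 1)
        vectors[name] = np.array([float(v) for v in rest.split()])
    assert lines[7] == "loadings"
    loadings = np.array([[float(v) for v in line.split()] for line in lines[8:]])
    return PCSpace(
        center=vectors["center"],
        scale=vectors["scale"],
        loadings=loadings,
        component_variances=vectors["component_variances"],
        explained_share=vectors["explained_share"],
        standardised=bool(int(head["standardised"])),
    )
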