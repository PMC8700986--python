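"""The three per-predictand prediction strategies.

* ``global``: for each predictand, a PLSR equation fitted on all remaining
  samples, with the factor count chosen by leave-one-out cross-validation
  within those samples (the benchmark).
* ``local_shenk``: the LOCAL strategy of Shenk & Westerhaus — a fixed
  number of neighbours ranked by Pearson correlation with the predictand's
  absorbance vector, and a fixed factor count (no cross-validation).
* ``local_changepoint``: neighbours are the samples before the first
  changepoint (of the sorted Mahalanobis distances in PC space) that keeps
  at least ``min_neighbours``; the factor count is then chosen by
  leave-one-out cross-validation within the neighbour set.

Every prediction is out-of-sample: the predictand's trait value never
enters the training set of the model that predicts it, and the returned
details carry the training identifiers so this can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import changepoint as cpt
from . import pca, pls
from .io import SpectralDataset

__all__ = [
    "ApproachConfig",
    "NeighbourSelection",
    "PredictionDetail",
    "select_neighbours_changepoint",
    "select_neighbours_shenk",
    "predict_one",
    "predict_one_detailed",
    "predict_all",
]

logger = logging.getLogger("localpls.approaches")


@dataclass
class ApproachConfig:
    """Settings for one prediction strategy.

    ``standardise_spectra`` and ``n_pcs`` control the neighbour-selection
    geometry only (regression predictors are never standardised).
    ``pc_fit_scope`` chooses whether the PC space is fitted on the full
    dataset (the usual single global geometry) or refitted without the
    predictand for a strictly leakage-free geometry.
    """

    approach: Literal["global", "local_shenk", "local_changepoint"] = "local_changepoint"
    standardise_spectra: bool = True
    n_pcs: int = 4
    penalty: Literal["SIC", "MBIC"] = "MBIC"
    variance_mode: str = "difference_estimator"
    min_segment_length: int = 2
    min_neighbours: int = 20
    shenk_k: int = 50
    shenk_factors: int = 10
    max_factors: int = 20
    pc_fit_scope: Literal["full_dataset", "exclude_predictand"] = "full_dataset"

    def __post_init__(self) -> None:
        if self.approach not in ("global", "local_shenk", "local_changepoint"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.min_neighbours < 2:
            raise ValueError("min_neighbours must be >= 2")
        if self.max_factors < 1:
            raise ValueError("max_factors must be >= 1")

    def label(self) -> str:
        """Short deterministic setting label used in reports."""
        if self.approach == "global":
            return "global"
        if self.approach == "local_shenk":
            return f"local_k{self.shenk_k}_f{self.shenk_factors}"
        std = "std" if self.standardise_spectra else "raw"
        return f"cp_{std}_{self.penalty.lower()}"


@dataclass
class NeighbourSelection:
    """The training samples chosen for one predictand."""

    predictand_id: object
    neighbour_ids: np.ndarray
    rule: Literal["changepoint", "fixed_k", "all"]
    changepoint_index_used: int | None
    distances_or_correlations: np.ndarray

    @property
    def n_neighbours(self) -> int:
        return len(self.neighbour_ids)


@dataclass
class PredictionDetail:
    """One out-of-sample prediction with its audit trail."""

    predictand_id: object
    trait: str
    value: float
    n_factors: int
    training_ids: np.ndarray
    selection: NeighbourSelection | None = None
    rmsecv_by_factors: np.ndarray | None = field(default=None, repr=False)


def _selection_space(ds: SpectralDataset, predictand_idx: int, cfg: ApproachConfig):
    """PC space and scores used for neighbour geometry, honouring scope."""
    if cfg.pc_fit_scope == "exclude_predictand":
        mask = np.ones(ds.n_samples, dtype=bool)
        mask[predictand_idx] = False
        space = pca.fit_pc_space(
            ds.spectra[mask], standardise=cfg.standardise_spectra, n_components=cfg.n_pcs
        )
    else:
        space = pca.fit_pc_space(
            ds.spectra, standardise=cfg.standardise_spectra, n_components=cfg.n_pcs
        )
    return space, pca.project(space, ds.spectra)


def select_neighbours_changepoint(
    ds: SpectralDataset,
    predictand_id,
    cfg: ApproachConfig,
    space: pca.PCSpace | None = None,
    scores: np.ndarray | None = None,
) -> NeighbourSelection:
    """Data-driven neighbour count from a changepoint of sorted distances.

    Candidates are ordered by ascending Mahalanobis distance to the
    predictand (ties by dataset order); PELT runs on the sorted vector and
    the neighbour count is the first changepoint index of at least
    ``cfg.min_neighbours``.  When no changepoint qualifies the selection
    falls back to all candidates (a flat distance profile means no local
    structure), recorded as rule ``"all"``.

    A fitted ``space``/``scores`` pair may be passed to reuse one geometry
    across predictands.
    """
    j = ds.index_of(predictand_id)
    n = ds.n_samples
    if n < cfg.min_neighbours + 2:
        raise ValueError(
            f"need at least {cfg.min_neighbours + 2} samples, have {n}"
        )
    if space is None or scores is None:
        space, scores = _selection_space(ds, j, cfg)
    others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
    d = pca.mahalanobis(space, scores[others], scores[j])
    order = np.argsort(d, kind="stable")  # stable -> ties in dataset order
    d_sorted = d[order]
    cp_cfg = cpt.ChangepointConfig(
        method="PELT",
        penalty=cfg.penalty,
        variance_mode=cfg.variance_mode,
        min_segment_length=cfg.min_segment_length,
    )
    result = cpt.detect_pelt(d_sorted, cp_cfg)
    chosen = next(
        (tau for tau in result.changepoints if tau >= cfg.min_neighbours), None
    )
    if chosen is None:
        logger.warning(
            "no changepoint at or beyond %d neighbours for %s; using all "
            "%d candidates",
            cfg.min_neighbours,
            predictand_id,
            len(others),
        )
        return NeighbourSelection(
            predictand_id=predictand_id,
            neighbour_ids=ds.sample_ids[others[order]],
            rule="all",
            changepoint_index_used=None,
            distances_or_correlations=d_sorted,
        )
    return NeighbourSelection(
        predictand_id=predictand_id,
        neighbour_ids=ds.sample_ids[others[order[:chosen]]],
        rule="changepoint",
        changepoint_index_used=int(chosen),
        distances_or_correlations=d_sorted[:chosen],
    )


def select_neighbours_shenk(
    ds: SpectralDataset,
    predictand_id,
    cfg: ApproachConfig,
) -> NeighbourSelection:
    """Fixed-size neighbour set by Pearson correlation of absorbance vectors.

    The top ``cfg.shenk_k`` candidates by correlation with the predictand
    spectrum are selected (ties by dataset order).  Zero-variance candidate
    spectra have undefined correlation and are excluded with a warning.
    """
    j = ds.index_of(predictand_id)
    n = ds.n_samples
    if cfg.shenk_k > n - 1:
        raise ValueError(
            f"shenk_k={cfg.shenk_k} exceeds the {n - 1} available candidates"
        )
    x = ds.spectra[j]
    if np.ptp(x) == 0:
        raise ValueError(f"predictand {predictand_id!r} has a constant spectrum")
    others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
    Xo = ds.spectra[others]
    sd = Xo.std(axis=1)
    valid = sd > 0
    if not valid.all():
        logger.warning(
            "excluding %d zero-variance candidate spectra from correlation "
            "ranking",
            int((~valid).sum()),
        )
    Xo = Xo[valid]
    others = others[valid]
    if cfg.shenk_k > len(others):
        raise ValueError(
            f"shenk_k={cfg.shenk_k} exceeds the {len(others)} available candidates"
        )
    xc = x - x.mean()
    Xoc = Xo - Xo.mean(axis=1, keepdims=True)
    corr = (Xoc @ xc) / (np.linalg.norm(Xoc, axis=1) * np.linalg.norm(xc))
    order = np.argsort(-corr, kind="stable")[: cfg.shenk_k]
    return NeighbourSelection(
        predictand_id=predictand_id,
        neighbour_ids=ds.sample_ids[others[order]],
        rule="fixed_k",
        changepoint_index_used=None,
        distances_or_correlations=corr[order],
    )


def _fit_and_predict(
    ds: SpectralDataset,
    trait: str,
    train_idx: np.ndarray,
    predictand_idx: int,
    cfg: ApproachConfig,
    fixed_factors: int | None,
):
    X = ds.spectra[train_idx]
    y = ds.traits[trait].to_numpy(dtype=float)[train_idx]
    if np.isnan(y).any():
        raise ValueError(f"trait {trait!r} has missing values in the training set")
    if len(train_idx) < 3:
        raise ValueError("fewer than 3 training samples; cannot cross-validate")
    rmsecv = None
    if fixed_factors is None:
        cap = min(cfg.max_factors, len(train_idx) - 2, ds.n_wavelengths)
        cv = pls.select_factors_loocv(X, y, cap)
        n_factors = cv.chosen_factors
        rmsecv = cv.rmsecv_by_factors
    else:
        n_factors = min(fixed_factors, len(train_idx) - 1, ds.n_wavelengths)
    model = pls.fit_pls(X, y, n_factors, training_ids=ds.sample_ids[train_idx])
    value = float(pls.predict(model, ds.spectra[predictand_idx : predictand_idx + 1])[0])
    return value, n_factors, rmsecv


def predict_one_detailed(
    ds: SpectralDataset,
    predictand_id,
    trait: str,
    cfg: ApproachConfig,
) -> PredictionDetail:
    """Predict one sample's trait, returning the full audit trail."""
    j = ds.index_of(predictand_id)
    if cfg.approach == "global":
        train_idx = np.concatenate([np.arange(j), np.arange(j + 1, ds.n_samples)])
        selection = None
    elif cfg.approach == "local_shenk":
        selection = select_neighbours_shenk(ds, predictand_id, cfg)
        train_idx = np.array([ds.index_of(i) for i in selection.neighbour_ids])
    else:
        selection = select_neighbours_changepoint(ds, predictand_id, cfg)
        train_idx = np.array([ds.index_of(i) for i in selection.neighbour_ids])
    fixed = cfg.shenk_factors if cfg.approach == "local_shenk" else None
    value, n_factors, rmsecv = _fit_and_predict(ds, trait, train_idx, j, cfg, fixed)
    return PredictionDetail(
        predictand_id=predictand_id,
        trait=trait,
        value=value,
        n_factors=n_factors,
        training_ids=ds.sample_ids[train_idx],
        selection=selection,
        rmsecv_by_factors=rmsecv,
    )


def predict_one(ds: SpectralDataset, predictand_id, trait: str, cfg: ApproachConfig) -> float:
    """Out-of-sample prediction of ``trait`` for one predictand."""
    return predict_one_detailed(ds, predictand_id, trait, cfg).value


def _all_selections(ds: SpectralDataset, cfg: ApproachConfig) -> list[NeighbourSelection]:
    """Neighbour selections for every sample, reusing one PC geometry when
    the scope allows it (selections are trait-independent)."""
    if cfg.approach == "local_shenk":
        return [select_neighbours_shenk(ds, sid, cfg) for sid in ds.sample_ids]
    if cfg.pc_fit_scope == "full_dataset":
        space = pca.fit_pc_space(
            ds.spectra, standardise=cfg.standardise_spectra, n_components=cfg.n_pcs
        )
        scores = pca.project(space, ds.spectra)
        return [
            select_neighbours_changepoint(ds, sid, cfg, space=space, scores=scores)
            for sid in ds.sample_ids
        ]
    return [select_neighbours_changepoint(ds, sid, cfg) for sid in ds.sample_ids]


def predict_all(
    ds: SpectralDataset,
    trait: str,
    cfg: ApproachConfig,
    selections: list[NeighbourSelection] | None = None,
) -> list[PredictionDetail]:
    """Out-of-sample predictions of ``trait`` for every sample.

    Equivalent to calling :func:`predict_one_detailed` per sample but much
    faster: the global approach shares its pair-deleted inner-CV fits across
    predictands, and the local approaches reuse one neighbour geometry.
    Precomputed ``selections`` (from a previous trait) may be passed in.
    """
    y = ds.traits[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"trait {trait!r} has missing values; edit the dataset first")
    if cfg.approach == "global":
        cap = min(cfg.max_factors, ds.n_samples - 3, ds.n_wavelengths)
        yhat, factors = pls.loo_global_benchmark(ds.spectra, y, cap)
        all_ids = ds.sample_ids
        return [
            PredictionDetail(
                predictand_id=sid,
                trait=trait,
                value=float(yhat[j, 0]),
                n_factors=int(factors[j, 0]),
                training_ids=np.delete(all_ids, j),
            )
            for j, sid in enumerate(all_ids)
        ]
    if selections is None:
        selections = _all_selections(ds, cfg)
    fixed = cfg.shenk_factors if cfg.approach == "local_shenk" else None
    details = []
    index = {sid: j for j, sid in enumerate(ds.sample_ids)}
    for j, sel in enumerate(selections):
        train_idx = np.array([index[i] for i in sel.neighbour_ids])
        value, n_factors, rmsecv = _fit_and_predict(ds, trait, train_idx, j, cfg, fixed)
        details.append(
            PredictionDetail(
                predictand_id=ds.sample_ids[j],
                trait=trait,
                value=value,
                n_factors=n_factors,
                training_ids=ds.sample_ids[train_idx],
                selection=sel,
                rmsecv_by_factors=rmsecv,
            )
        )
    return details
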