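"""Leave-one-out benchmarking of the prediction strategies.

For every sample, trait and strategy setting the harness produces one
out-of-sample prediction and aggregates:

* RMSEV - root mean square error over the validation (held-out) predictions;
* r - Pearson correlation between true and predicted values;
* residual vectors (for diagnostic plots);
* neighbour-count and factor-count summaries;
* the same error metrics restricted to the "edge" subsets: the samples
  with the greatest Mahalanobis distance from the centre of the global
  four-component standardised PC space (5% and 10% by default), where a
  local strategy has the most room to help.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pca
from .approaches import ApproachConfig, PredictionDetail, _all_selections, predict_all
from .io import SpectralDataset

__all__ = [
    "EvaluationReport",
    "rmsev",
    "pearson_r",
    "edge_subset",
    "default_grid",
    "run_benchmark",
    "leakage_audit",
]


def rmsev(y_true, y_pred) -> float:
    """Root mean square error of validation predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson_r(y_true, y_pred) -> float:
    """Sample Pearson correlation; NaN (with a warning) if degenerate."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        import warnings

        warnings.warn("zero-variance input; correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def edge_subset(ds: SpectralDataset, space: pca.PCSpace, fraction: float) -> np.ndarray:
    """Sample ids of the ``fraction`` most outlying spectra in PC space.

    Size is ``round(fraction * n)`` with half away from zero (e.g. 5% of
    348 -> 17); ties at the cut are broken by dataset order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = ds.n_samples
    k = int(math.floor(fraction * n + 0.5))
    if k < 2:
        raise ValueError(f"edge subset of {k} samples is too small")
    d = pca.center_distances(space, pca.project(space, ds.spectra))
    order = np.argsort(-d, kind="stable")
    return ds.sample_ids[order[:k]]


def default_grid(max_factors: int = 20, min_neighbours: int = 20) -> list[ApproachConfig]:
    """The standard comparison design: 1 global + 9 LOCAL + 4 changepoint.

    LOCAL crosses 25/50/100 neighbours with 5/10/20 factors; the
    changepoint strategy crosses SIC/MBIC penalties with standardised and
    unstandardised spectra.
    """
    grid = [ApproachConfig(approach="global", max_factors=max_factors)]
    for k in (25, 50, 100):
        for f in (5, 10, 20):
            grid.append(
                ApproachConfig(approach="local_shenk", shenk_k=k, shenk_factors=f)
            )
    for std in (True, False):
        for pen in ("MBIC", "SIC"):
            grid.append(
                ApproachConfig(
                    approach="local_changepoint",
                    standardise_spectra=std,
                    penalty=pen,
                    max_factors=max_factors,
                    min_neighbours=min_neighbours,
                )
            )
    return grid


@dataclass
class EvaluationReport:
    """Benchmark output: one table row per trait x setting, plus residuals."""

    table: pd.DataFrame
    residuals: pd.DataFrame
    edge_ids: dict[float, np.ndarray]


def _summaries(details: list[PredictionDetail]):
    counts = [d.selection.n_neighbours for d in details if d.selection is not None]
    factors = [d.n_factors for d in details]
    out = {}
    if counts:
        out.update(
            neighbours_mean=float(np.mean(counts)),
            neighbours_min=int(np.min(counts)),
            neighbours_max=int(np.max(counts)),
        )
    else:
        out.update(neighbours_mean=np.nan, neighbours_min=np.nan, neighbours_max=np.nan)
    out.update(
        factors_median=float(np.median(factors)),
        factors_min=int(np.min(factors)),
        factors_max=int(np.max(factors)),
    )
    return out


def run_benchmark(
    ds: SpectralDataset,
    configs: list[ApproachConfig] | None = None,
    traits: list[str] | None = None,
    edge_fractions: tuple[float, ...] = (0.05, 0.10),
) -> EvaluationReport:
    """Run the full leave-one-out comparison.

    Deterministic given the dataset and configs.  Edge subsets are always
    defined in the standardised four-component PC space of the full
    dataset, regardless of the setting being evaluated; neighbour
    selections are reused across traits (they depend on spectra only).
    """
    if ds.n_samples < 10:
        raise ValueError("benchmark needs at least 10 samples")
    configs = configs if configs is not None else default_grid()
    traits = traits if traits is not None else ds.trait_names
    edge_space = pca.fit_pc_space(
        ds.spectra, standardise=True, n_components=min(4, ds.n_samples - 1)
    )
    edge_ids = {f: edge_subset(ds, edge_space, f) for f in edge_fractions}
    edge_masks = {
        f: np.isin(ds.sample_ids, ids).astype(bool) for f, ids in edge_ids.items()
    }
    selection_cache: dict[tuple, list] = {}
    rows = []
    residual_rows = []
    for cfg in configs:
        label = cfg.label()
        sel_key = None
        if cfg.approach != "global":
            sel_key = (
                cfg.approach,
                cfg.standardise_spectra,
                cfg.penalty if cfg.approach == "local_changepoint" else None,
                cfg.shenk_k if cfg.approach == "local_shenk" else None,
                cfg.n_pcs,
                cfg.min_neighbours,
                cfg.pc_fit_scope,
                cfg.variance_mode,
            )
            if sel_key not in selection_cache:
                selection_cache[sel_key] = _all_selections(ds, cfg)
        for trait in traits:
            details = predict_all(
                ds,
                trait,
                cfg,
                selections=None if sel_key is None else selection_cache[sel_key],
            )
            y = ds.traits[trait].to_numpy(dtype=float)
            yhat = np.array([d.value for d in details])
            resid = y - yhat
            row = {
                "trait": trait,
                "approach": cfg.approach,
                "setting": label,
                "n": ds.n_samples,
                "rmsev": rmsev(y, yhat),
                "r": pearson_r(y, yhat),
            }
            row.update(_summaries(details))
            for f, mask in edge_masks.items():
                pct = int(round(100 * f))
                row[f"rmsev_edge{pct}"] = rmsev(y[mask], yhat[mask])
                row[f"r_edge{pct}"] = pearson_r(y[mask], yhat[mask])
            rows.append(row)
            for sid, r_val in zip(ds.sample_ids, resid):
                residual_rows.append(
                    {"sample_id": sid, "trait": trait, "setting": label, "residual": r_val}
                )
    table = pd.DataFrame(rows)
    residuals = pd.DataFrame(residual_rows)
    return EvaluationReport(table=table, residuals=residuals, edge_ids=edge_ids)


def leakage_audit(details: list[PredictionDetail]) -> bool:
    """True iff no prediction's training set contains its own predictand."""
    for d in details:
        if d.predictand_id in set(d.training_ids):
            return False
        if d.selection is not None and d.predictand_id in set(d.selection.neighbour_ids):
            return False
    return True
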