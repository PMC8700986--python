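"""Spectral dataset container, delimited-text I/O and the editing pipeline.

The editing pipeline mirrors the standard preparation of mid-infrared milk
spectra for calibration work, executed in a fixed order:

1. animal de-duplication (keep, per animal, the record farthest from the
   centre of the dataset-wide PC space, to maximise retained variability);
2. removal of high-noise wavenumber regions (the water-related windows
   1580-1710 and 2990-3690 cm^-1 and everything above 3822 cm^-1);
3. transmittance -> absorbance transform, ``A = log10(1/T)`` (only when the
   input is transmittance);
4. per-trait outlier removal (>3 SD from the trait mean, single pass) and
   restriction to samples with complete trait records.

Each stage logs row/column counts so an edited dataset can be audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import pca

__all__ = [
    "SpectralDataset",
    "PreprocessConfig",
    "DEFAULT_DISCARD_WINDOWS",
    "to_absorbance",
    "trim_regions",
    "remove_trait_outliers",
    "deduplicate_animals",
    "edit_pipeline",
    "load_dataset",
    "write_dataset",
]

logger = logging.getLogger("localpls.io")

#: High-noise regions discarded from milk mid-infrared spectra (cm^-1).
#: Closed intervals; the last window is open-ended above 3822 cm^-1.
DEFAULT_DISCARD_WINDOWS: tuple[tuple[float, float], ...] = (
    (1580.0, 1710.0),
    (2990.0, 3690.0),
    (3822.0, math.inf),
)


@dataclass
class SpectralDataset:
    """A set of spectra with sample/animal identifiers and trait values.

    Attributes
    ----------
    wavenumbers : (p,) strictly increasing grid, cm^-1.
    spectra : (n, p) matrix, absorbance units (or transmittance before the
        editing pipeline converts it).
    sample_ids : (n,) unique sample identifiers.
    animal_ids : (n,) animal identifiers; repeats allowed before editing.
    traits : DataFrame indexed by sample id, one column per trait; missing
        values allowed before editing.
    meta : free-form provenance dictionary (e.g. simulation ground truth);
        not serialised.
    """

    wavenumbers: np.ndarray
    spectra: np.ndarray
    sample_ids: np.ndarray
    animal_ids: np.ndarray
    traits: pd.DataFrame
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        n, p = self.spectra.shape
        if len(self.wavenumbers) != p:
            raise ValueError("wavenumber count does not match spectra columns")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if len(self.sample_ids) != n or len(self.animal_ids) != n:
            raise ValueError("id vectors must match the spectra row count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        # Align the trait table to the spectra rows (missing rows -> NaN).
        self.traits = self.traits.reindex(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.spectra.shape[1]

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def index_of(self, sample_id) -> int:
        idx = np.nonzero(self.sample_ids == sample_id)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return int(idx[0])

    def subset_rows(self, rows) -> "SpectralDataset":
        """Row subset by boolean mask or integer positions (order preserved)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.nonzero(rows)[0]
        return SpectralDataset(
            wavenumbers=self.wavenumbers,
            spectra=self.spectra[rows],
            sample_ids=self.sample_ids[rows],
            animal_ids=self.animal_ids[rows],
            traits=self.traits.iloc[rows],
            meta=dict(self.meta),
        )

    def subset_columns(self, keep) -> "SpectralDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return SpectralDataset(
            wavenumbers=self.wavenumbers[keep],
            spectra=self.spectra[:, keep],
            sample_ids=self.sample_ids,
            animal_ids=self.animal_ids,
            traits=self.traits,
            meta=dict(self.meta),
        )


@dataclass
class PreprocessConfig:
    """Settings for the editing pipeline.

    ``discard_windows`` are closed wavenumber intervals; an upper bound of
    ``inf`` expresses an open-ended "everything above" window.
    """

    discard_windows: Sequence[tuple[float, float]] = DEFAULT_DISCARD_WINDOWS
    outlier_sd: float = 3.0
    min_traits_complete: bool = True
    deduplicate: bool = True
    n_pcs_dedup: int = 4
    standardise_dedup: bool = True

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        windows = sorted((float(a), float(b)) for a, b in self.discard_windows)
        for (a, b) in windows:
            if b < a:
                raise ValueError(f"invalid discard window ({a}, {b})")
        for (_, b1), (a2, _) in zip(windows, windows[1:]):
            if a2 <= b1:
                raise ValueError("discard windows overlap")
        self.discard_windows = tuple(windows)
        if self.n_pcs_dedup < 1:
            raise ValueError("n_pcs_dedup must be positive")


def to_absorbance(
    transmittance: np.ndarray,
    sample_ids=None,
    wavenumbers=None,
) -> np.ndarray:
    """Elementwise ``log10(1/T)`` transmittance-to-absorbance transform.

    Raises ``ValueError`` naming the first offending sample and wavenumber
    when any transmittance value is non-positive.
    """
    T = np.asarray(transmittance, dtype=float)
    bad = T <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        sid = sample_ids[i] if sample_ids is not None else f"row {i}"
        wn = f"{wavenumbers[j]} cm^-1" if wavenumbers is not None else f"column {j}"
        raise ValueError(
            f"non-positive transmittance {T[i, j]!r} for sample {sid} at {wn}; "
            "absorbance is undefined"
        )
    return np.log10(1.0 / T)


def trim_regions(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Drop wavelengths inside any discard window; column order preserved."""
    keep = np.ones(ds.n_wavelengths, dtype=bool)
    for lo, hi in cfg.discard_windows:
        inside = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
        logger.info(
            "trim_regions: window [%g, %g] removes %d wavelengths", lo, hi, inside.sum()
        )
        keep &= ~inside
    if not keep.any():
        raise ValueError("discard windows remove every wavelength")
    return ds.subset_columns(keep)


def remove_trait_outliers(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Single-pass >k-SD trait outlier removal, then completeness filter.

    The mean and (n-1 denominator) SD of each trait are computed once on the
    pre-filter values; samples whose value deviates more than
    ``cfg.outlier_sd`` SDs are dropped.  A zero-variance trait removes
    nothing.  Samples missing any trait are then dropped when
    ``min_traits_complete`` is on.
    """
    keep = np.ones(ds.n_samples, dtype=bool)
    for name in ds.trait_names:
        values = ds.traits[name].to_numpy(dtype=float)
        present = ~np.isnan(values)
        if present.sum() < 2:
            raise ValueError(f"trait {name!r} has fewer than 2 non-missing values")
        mean = values[present].mean()
        sd = values[present].std(ddof=1)
        if sd == 0:
            logger.info("remove_trait_outliers: %s has zero variance, no removals", name)
            continue
        out = present & (np.abs(values - mean) > cfg.outlier_sd * sd)
        logger.info(
            "remove_trait_outliers: %s removes %d samples (>%g SD)",
            name,
            out.sum(),
            cfg.outlier_sd,
        )
        keep &= ~out
    if cfg.min_traits_complete:
        complete = ~ds.traits.isna().any(axis=1).to_numpy()
        logger.info(
            "remove_trait_outliers: completeness filter removes %d samples",
            int((~complete & keep).sum()),
        )
        keep &= complete
    return ds.subset_rows(keep)


def deduplicate_animals(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Keep one record per animal: the one farthest from the PC-space centre.

    The PC space (``cfg.n_pcs_dedup`` components, standardised by default)
    is fitted on the current spectra; for each duplicated animal the record
    with the greatest Mahalanobis distance from the centre is retained
    (ties broken by first occurrence), maximising retained variability.
    """
    animals, counts = np.unique(ds.animal_ids.astype(str), return_counts=True)
    if (counts == 1).all():
        return ds
    n_pcs = min(cfg.n_pcs_dedup, ds.n_samples - 1, ds.n_wavelengths)
    if n_pcs < cfg.n_pcs_dedup:
        logger.warning("deduplicate_animals: lowering PC count to %d", n_pcs)
    space = pca.fit_pc_space(
        ds.spectra,
        standardise=cfg.standardise_dedup,
        n_components=n_pcs,
        on_deficient_rank="truncate",
    )
    dist = pca.center_distances(space, pca.project(space, ds.spectra))
    keep = np.zeros(ds.n_samples, dtype=bool)
    animal_str = ds.animal_ids.astype(str)
    for animal in animals:
        rows = np.nonzero(animal_str == animal)[0]
        keep[rows[np.argmax(dist[rows])]] = True
    logger.info(
        "deduplicate_animals: %d records collapse to %d animals",
        ds.n_samples,
        keep.sum(),
    )
    return ds.subset_rows(keep)


def edit_pipeline(
    ds: SpectralDataset,
    cfg: PreprocessConfig | None = None,
    is_transmittance: bool = False,
) -> tuple[SpectralDataset, list[str]]:
    """Run the full editing pipeline in its fixed order; returns a log.

    Order: de-duplication, region trimming, absorbance transform (if the
    input is transmittance), trait outlier/completeness filter.  The
    pipeline is idempotent on its own output.
    """
    cfg = cfg or PreprocessConfig()
    log: list[str] = [f"input: {ds.n_samples} samples x {ds.n_wavelengths} wavelengths"]
    if cfg.deduplicate:
        ds = deduplicate_animals(ds, cfg)
        log.append(f"after deduplication: {ds.n_samples} samples")
    ds = trim_regions(ds, cfg)
    log.append(f"after region trimming: {ds.n_wavelengths} wavelengths")
    if is_transmittance:
        ds = replace(
            ds,
            spectra=to_absorbance(ds.spectra, ds.sample_ids, ds.wavenumbers),
            traits=ds.traits,
        )
        log.append("transmittance converted to absorbance")
    ds = remove_trait_outliers(ds, cfg)
    log.append(f"after trait outlier/completeness filter: {ds.n_samples} samples")
    return ds, log


# ---------------------------------------------------------------------------
# Delimited-text I/O.
#
# Spectra CSV: columns `sample_id, animal_id, <wavenumber_1>, ...`.
# Trait CSV: `sample_id` plus one column per trait; empty fields are missing.
# ---------------------------------------------------------------------------


def load_dataset(spectra_path, traits_path) -> SpectralDataset:
    """Read a dataset from the spectra/trait CSV pair."""
    spec = pd.read_csv(spectra_path, dtype={"sample_id": str, "animal_id": str})
    if list(spec.columns[:2]) != ["sample_id", "animal_id"]:
        raise ValueError("spectra CSV must start with sample_id, animal_id columns")
    wavenumbers = np.array([float(c) for c in spec.columns[2:]])
    traits = pd.read_csv(traits_path, dtype={"sample_id": str}).set_index("sample_id")
    return SpectralDataset(
        wavenumbers=wavenumbers,
        spectra=spec.iloc[:, 2:].to_numpy(dtype=float),
        sample_ids=spec["sample_id"].to_numpy(dtype=object),
        animal_ids=spec["animal_id"].to_numpy(dtype=object),
        traits=traits,
    )


def write_dataset(ds: SpectralDataset, spectra_path, traits_path) -> None:
    """Write the spectra/trait CSV pair in the dialect ``load_dataset`` reads."""
    spec = pd.DataFrame(ds.spectra, columns=[repr(float(w)) for w in ds.wavenumbers])
    spec.insert(0, "animal_id", ds.animal_ids)
    spec.insert(0, "sample_id", ds.sample_ids)
    spec.to_csv(spectra_path, index=False, float_format="%.12g")
    traits = ds.traits.copy()
    traits.index.name = "sample_id"
    traits.to_csv(traits_path, float_format="%.12g")
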