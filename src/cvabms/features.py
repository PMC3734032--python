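"""Band-power feature extraction from source-level Fourier coefficients.

Each feature-set "model" fractionates the 3-90 Hz spectrum into ``d``
frequency bands; the feature vector of a trial is the mean power
``s * conj(s)`` over the bins of each band.  Before model fitting, each
band is mean-removed (pooled across conditions) and scaled to unit
variance so that bands with very different absolute power contribute
equally.

Band membership is half-open, ``low <= f < high``, except that the upper
edge of the final band of a table is included (so a 90 Hz bin belongs to
the top band).  Shared edges such as 10 Hz in "3-10" and "10-30" therefore
go to the higher band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .beamformer import TrialSpectra
from .errors import (
    DegenerateFeatureError,
    EmptyBandError,
    ShapeError,
    UnknownModelError,
    ValidationError,
)

__all__ = [
    "BandTable",
    "FeatureMatrix",
    "DEFAULT_BAND_TABLES",
    "default_band_table",
    "band_table_from_yaml",
    "band_power",
    "normalize_features",
]

#: Built-in fractionations of the 3-90 Hz spectrum, keyed by dimension d.
DEFAULT_BAND_TABLES: dict[int, tuple[tuple[float, float], ...]] = {
    1: ((3, 90),),
    3: ((3, 10), (10, 30), (30, 90)),
    5: ((3, 8), (8, 12), (12, 30), (30, 50), (50, 90)),
    7: ((3, 5), (5, 8), (8, 12), (12, 20), (20, 30), (30, 50), (50, 90)),
    9: (
        (3, 5), (5, 8), (8, 10), (10, 12), (12, 20),
        (20, 30), (30, 40), (40, 50), (50, 90),
    ),
    11: (
        (3, 5), (5, 8), (8, 10), (10, 12), (12, 20), (20, 30),
        (30, 40), (40, 50), (50, 60), (60, 70), (70, 90),
    ),
}


@dataclass(frozen=True)
class BandTable:
    """Ordered, non-overlapping frequency bands defining a feature set."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        if not bands:
            raise ValidationError("band table must contain at least one band")
        for lo, hi in bands:
            if not lo < hi:
                raise ValidationError(f"band ({lo}, {hi}) has low >= high")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi:
                raise ValidationError("bands must be ordered and non-overlapping")
        object.__setattr__(self, "bands", bands)

    @property
    def d(self) -> int:
        return len(self.bands)

    @property
    def span(self) -> tuple[float, float]:
        return self.bands[0][0], self.bands[-1][1]

    def bin_masks(self, bin_frequencies: np.ndarray) -> list[np.ndarray]:
        """Boolean bin membership per band (half-open; last edge closed)."""
        f = np.asarray(bin_frequencies, dtype=float)
        masks = []
        top = self.bands[-1][1]
        for lo, hi in self.bands:
            mask = (f >= lo) & (f < hi)
            if hi == top:
                mask |= f == top
            if not mask.any():
                raise EmptyBandError(
                    f"band ({lo}, {hi}) Hz contains no bins of the supplied grid"
                )
            masks.append(mask)
        return masks


@dataclass
class FeatureMatrix:
    """Trials x d matrix of band powers, raw or normalized."""

    values: np.ndarray
    band_table: BandTable
    condition_labels: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        lab = np.asarray(self.condition_labels).ravel()
        if v.ndim != 2:
            raise ShapeError(f"feature matrix must be 2-D, got shape {v.shape}")
        if v.shape[1] != self.band_table.d:
            raise ShapeError(
                f"{v.shape[1]} feature columns for a {self.band_table.d}-band table"
            )
        if lab.size != v.shape[0]:
            raise ShapeError(f"{lab.size} labels for {v.shape[0]} trials")
        self.values = v
        self.condition_labels = lab

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def default_band_table(d: int) -> BandTable:
    """Built-in band table for dimension ``d`` in {1, 3, 5, 7, 9, 11}."""
    try:
        bands = DEFAULT_BAND_TABLES[int(d)]
    except (KeyError, TypeError, ValueError):
        raise UnknownModelError(
            f"no built-in band table for d={d!r}; defined dimensions are "
            f"{sorted(DEFAULT_BAND_TABLES)}"
        ) from None
    return BandTable(bands=bands)


def band_table_from_yaml(source) -> BandTable:
    """Read a band table from a YAML file path, stream, or string.

    Expected layout::

        bands: [[3, 10], [10, 30], [30, 90]]
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        try:
            with open(source, "r") as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "bands" not in doc:
        raise ValidationError("band YAML must contain a 'bands' key")
    return BandTable(bands=tuple(tuple(b) for b in doc["bands"]))


def band_power(source: TrialSpectra, table: BandTable) -> FeatureMatrix:
    """Raw mean power per band: entry (trial, band) = mean_j s_j conj(s_j)."""
    if not source.is_source_level:
        raise ShapeError(
            "band_power expects source-level spectra (trials, bins); "
            "project sensor data first"
        )
    masks = table.bin_masks(source.bin_frequencies)
    power = (source.coeffs * np.conj(source.coeffs)).real
    values = np.column_stack([power[:, m].mean(axis=1) for m in masks])
    return FeatureMatrix(
        values=values,
        band_table=table,
        condition_labels=source.condition_labels,
        normalized=False,
    )


def normalize_features(raw: FeatureMatrix) -> FeatureMatrix:
    """Mean-remove and variance-normalize each band, pooled over conditions.

    The mean and (population, i.e. divide-by-n) standard deviation are taken
    over all trials of all conditions, matching the maximum-likelihood
    covariance convention used in the BIC scoring.  Idempotent.
    """
    v = raw.values
    mean = v.mean(axis=0)
    std = v.std(axis=0)  # population convention
    scale = np.abs(v).max(axis=0)
    bad = std <= 1e-12 * np.maximum(scale, 1.0)
    if bad.any():
        names = ", ".join(
            f"({lo}-{hi} Hz)" for flag, (lo, hi) in zip(bad, raw.band_table.bands) if flag
        )
        raise DegenerateFeatureError(
            f"zero-variance band power in band(s) {names}; cannot normalize"
        )
    return FeatureMatrix(
        values=(v - mean) / std,
        band_table=raw.band_table,
        condition_labels=raw.condition_labels,
        normalized=True,
    )
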