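"""Voxelwise subject scoring and group-level model-frequency maps.

For each source-space voxel and each candidate feature set (band table of
dimension ``d``) the subject-level score is the BIC log Bayes factor of a
single-canonical-vector CVA model against the null, computed from the
voxel's normalized band powers and the trial condition labels.  Stacking
these scores over subjects gives, per voxel, an N x K evidence table
(the null enters as a column of exact zeros) on which random-effects
Bayesian model selection yields expected-frequency and
exceedance-probability maps, plus a winner map (model with the largest
expected frequency; ties go to the lower model index, null first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cva import fit_cva
from .errors import ShapeError, ValidationError
from .features import BandTable, FeatureMatrix, normalize_features
from .rfx import EvidenceTable, exceedance_probabilities, fit_rfx

__all__ = [
    "VoxelGrid",
    "SubjectSourceData",
    "GroupMapSet",
    "score_subject_voxelwise",
    "group_maps",
    "summarize_roi",
    "write_maps_nifti",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("subject", "voxel", "model_d", "logbf")


@dataclass
class VoxelGrid:
    """Source-space voxel identifiers with integer grid coordinates."""

    voxel_ids: tuple[str, ...]
    coords: np.ndarray
    spacing_mm: float = 10.0
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=int)
        ids = tuple(str(v) for v in self.voxel_ids)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ShapeError(f"coords must be (voxels, 3), got {coords.shape}")
        if coords.shape[0] != len(ids):
            raise ShapeError(f"{len(ids)} ids for {coords.shape[0]} coordinates")
        if len({tuple(c) for c in coords}) != coords.shape[0]:
            raise ValidationError("voxel coordinates must be unique")
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (len(ids),):
                raise ShapeError(f"ROI mask {name!r} does not match the grid")
            self.roi_masks[name] = mask
        self.voxel_ids = ids
        self.coords = coords

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class SubjectSourceData:
    """Source-level coefficients for one subject across a voxel set.

    ``coeffs`` has shape (voxels, trials, bins).
    """

    subject_id: str
    coeffs: np.ndarray
    bin_frequencies: np.ndarray
    condition_labels: np.ndarray
    voxel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=complex)
        f = np.asarray(self.bin_frequencies, dtype=float).ravel()
        lab = np.asarray(self.condition_labels).ravel()
        ids = tuple(str(v) for v in self.voxel_ids)
        if c.ndim != 3:
            raise ShapeError(f"coeffs must be (voxels, trials, bins), got {c.shape}")
        if c.shape[0] != len(ids):
            raise ShapeError(f"{len(ids)} voxel ids for {c.shape[0]} voxel arrays")
        if c.shape[2] != f.size:
            raise ShapeError("bin count mismatch between coeffs and bin_frequencies")
        if lab.size != c.shape[1]:
            raise ShapeError(f"{lab.size} labels for {c.shape[1]} trials")
        self.coeffs = c
        self.bin_frequencies = f
        self.condition_labels = lab
        self.voxel_ids = ids


@dataclass
class GroupMapSet:
    """Group-level maps over the voxels that survived assembly."""

    voxel_ids: tuple[str, ...]
    model_names: tuple[str, ...]
    expected_frequency: np.ndarray  # voxels x models
    exceedance: np.ndarray  # voxels x models
    winner: np.ndarray  # voxel -> column index into model_names
    n_subjects: int
    excluded_voxels: tuple[str, ...] = ()

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def winner_names(self) -> np.ndarray:
        return np.asarray(self.model_names, dtype=object)[self.winner]


def _model_name(d: int) -> str:
    return f"model_{d}"  # model_0 is the null


def score_subject_voxelwise(
    subject: SubjectSourceData,
    band_tables: Mapping[int, BandTable],
    design: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-voxel, per-model logBF of the one-canonical-vector model vs null.

    Returns a DataFrame with columns (subject, voxel, model_d, logbf).  A
    voxel/model combination whose fit fails is recorded as missing (left
    out of the table) and counted in a log message, never fabricated.
    """
    if subject.coeffs.shape[1] == 0:
        raise ValidationError(f"subject {subject.subject_id!r} has zero trials")
    if not band_tables:
        raise ValidationError("no band tables supplied")
    X = subject.condition_labels if design is None else np.asarray(design)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != subject.coeffs.shape[1]:
        raise ShapeError("design rows must equal trial count")

    masks = {
        d: table.bin_masks(subject.bin_frequencies) for d, table in band_tables.items()
    }
    power = (subject.coeffs * np.conj(subject.coeffs)).real  # voxels x trials x bins
    rows = []
    n_failed = 0
    for v, vid in enumerate(subject.voxel_ids):
        pv = power[v]
        for d, table in band_tables.items():
            feats = np.column_stack([pv[:, m].mean(axis=1) for m in masks[d]])
            try:
                fm = normalize_features(
                    FeatureMatrix(
                        values=feats,
                        band_table=table,
                        condition_labels=subject.condition_labels,
                    )
                )
                res = fit_cva(X, fm, label=f"voxel {vid} d={d}")
            except ValidationError as exc:
                n_failed += 1
                logger.warning(
                    "voxel %s model d=%d failed for subject %s: %s",
                    vid, d, subject.subject_id, exc,
                )
                continue
            rows.append((subject.subject_id, vid, d, float(res.log_bf[1])))
    if n_failed:
        logger.info(
            "subject %s: %d voxel/model fits failed and were recorded as missing",
            subject.subject_id, n_failed,
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def _assemble_tables(
    records: pd.DataFrame, models: Sequence[int]
) -> tuple[list[str], dict[str, np.ndarray], list[str]]:
    """Per-voxel N x K evidence tables with a leading zero null column."""
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"records table lacks columns {sorted(missing)}")
    alt_models = sorted({int(m) for m in models if int(m) != 0})
    if not alt_models:
        raise ValidationError(
            "comparison set must contain at least one non-null model"
        )
    subjects = sorted(records["subject"].unique())
    voxels = list(dict.fromkeys(records["voxel"]))
    wide = records.pivot_table(
        index=["voxel", "subject"], columns="model_d", values="logbf", aggfunc="first"
    )
    tables: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for vid in voxels:
        try:
            block = wide.loc[vid]
        except KeyError:
            excluded.append(vid)
            continue
        block = block.reindex(index=subjects, columns=alt_models)
        if block.isna().any().any():
            excluded.append(vid)
            continue
        evid = np.column_stack([np.zeros(len(subjects)), block.to_numpy(float)])
        tables[vid] = evid
    if excluded:
        logger.info(
            "%d voxels excluded from group maps (missing subject records)",
            len(excluded),
        )
    return [_model_name(0)] + [_model_name(d) for d in alt_models], tables, excluded


def group_maps(
    records: pd.DataFrame,
    models: Sequence[int],
    alpha0: float | np.ndarray | None = None,
    n_exceedance_samples: int = 10_000,
    seed: int | None = None,
) -> GroupMapSet:
    """Voxelwise RFX-BMS over subject logBF records.

    ``models`` is the comparison set of feature dimensions; the null model
    always participates as a column of exact zeros (all scores are logBF
    against it).  Voxels missing for any subject are excluded with a
    logged count.
    """
    model_names, tables, excluded = _assemble_tables(records, models)
    if not tables:
        raise ValidationError("no voxel has complete records for all subjects")
    K = len(model_names)
    voxel_ids = tuple(tables.keys())
    xf = np.empty((len(voxel_ids), K))
    ep = np.empty((len(voxel_ids), K))
    n_subjects = next(iter(tables.values())).shape[0]
    rng = np.random.default_rng(seed)
    for i, vid in enumerate(voxel_ids):
        post = fit_rfx(
            EvidenceTable(values=tables[vid], model_names=tuple(model_names)),
            alpha0=alpha0,
        )
        xf[i] = post.expected_frequencies
        ep[i] = exceedance_probabilities(
            post,
            n_samples=n_exceedance_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    winner = np.argmax(xf, axis=1)  # first max -> lower index on ties
    return GroupMapSet(
        voxel_ids=voxel_ids,
        model_names=tuple(model_names),
        expected_frequency=xf,
        exceedance=ep,
        winner=winner,
        n_subjects=n_subjects,
        excluded_voxels=tuple(excluded),
    )


def summarize_roi(
    maps: GroupMapSet,
    mask: np.ndarray | Sequence[str] | None = None,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Region summary: threshold counts, winner counts, mean frequencies.

    ``mask`` may be a boolean array over ``maps.voxel_ids``, a collection
    of voxel ids, or None for all voxels.  Per model the table reports the
    count and percentage of masked voxels whose expected frequency exceeds
    ``threshold``, the count and percentage where the model wins, and the
    mask-averaged expected frequency.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    n = maps.n_voxels
    if mask is None:
        sel = np.ones(n, dtype=bool)
    else:
        mask_arr = np.asarray(mask)
        if mask_arr.dtype == bool:
            if mask_arr.shape != (n,):
                raise ShapeError("boolean mask must match the map voxel count")
            sel = mask_arr
        else:
            wanted = {str(v) for v in mask_arr.ravel()}
            sel = np.array([vid in wanted for vid in maps.voxel_ids])
    n_masked = int(sel.sum())
    if n_masked == 0:
        raise ValidationError("ROI mask selects no voxels")
    xf = maps.expected_frequency[sel]
    winner = maps.winner[sel]
    rows = []
    for k, name in enumerate(maps.model_names):
        above = int((xf[:, k] > threshold).sum())
        wins = int((winner == k).sum())
        rows.append(
            {
                "model": name,
                "n_voxels": n_masked,
                "n_above_threshold": above,
                "pct_above_threshold": 100.0 * above / n_masked,
                "n_winner": wins,
                "pct_winner": 100.0 * wins / n_masked,
                "mean_expected_frequency": float(xf[:, k].mean()),
            }
        )
    return pd.DataFrame(rows)


def write_maps_nifti(
    maps: GroupMapSet, grid: VoxelGrid, out_dir, prefix: str = "group"
) -> list[Path]:
    """Write expected-frequency (``*_xpm``) and exceedance (``*_epm``) volumes.

    One NIfTI-1 image per model per map type on the grid's bounding box,
    with untouched voxels set to NaN and the affine scaled by the grid
    spacing.  Falls back to a single CSV when voxel ids cannot be matched
    to the grid.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    id_to_coord = dict(zip(grid.voxel_ids, grid.coords))
    if not all(v in id_to_coord for v in maps.voxel_ids):
        path = out_dir / f"{prefix}_maps.csv"
        df = pd.DataFrame(
            maps.expected_frequency, columns=[f"{m}_xpm" for m in maps.model_names]
        )
        for k, m in enumerate(maps.model_names):
            df[f"{m}_epm"] = maps.exceedance[:, k]
        df.insert(0, "voxel", list(maps.voxel_ids))
        df.to_csv(path, index=False)
        return [path]

    coords = np.array([id_to_coord[v] for v in maps.voxel_ids])
    origin = coords.min(axis=0)
    shape = coords.max(axis=0) - origin + 1
    ijk = coords - origin
    affine = np.diag([grid.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = origin * grid.spacing_mm
    written = []
    for kind, data in (("xpm", maps.expected_frequency), ("epm", maps.exceedance)):
        for k, model in enumerate(maps.model_names):
            vol = np.full(shape, np.nan, dtype=np.float32)
            vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = data[:, k]
            img = nib.Nifti1Image(vol, affine)
            path = out_dir / f"{prefix}_{model}_{kind}.nii"
            nib.save(img, path)
            written.append(path)
    return written
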