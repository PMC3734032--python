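"""HDF5/CSV interchange for trial spectra, lead fields, and results.

No community on-disk standard covers per-trial complex Fourier
coefficients, so the package uses a plain HDF5 layout with named
datasets:

* sensor-level file: ``leadfields`` (voxels x channels x 3), ``cov``
  (channels x channels), ``coeffs`` (trials x channels x bins),
  ``freqs_hz``, ``labels``;
* source-level group file: one group per subject holding ``coeffs``
  (voxels x trials x bins), ``freqs_hz`` and ``labels``, plus top-level
  ``voxel_ids``, ``voxel_coords`` and ``spacing_mm``.

Evidence tables and voxelwise score records travel as CSV via pandas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .beamformer import LeadField, SensorCovariance, TrialSpectra
from .errors import ValidationError
from .maps import RECORD_COLUMNS, SubjectSourceData, VoxelGrid

__all__ = [
    "save_sensor_dataset",
    "load_sensor_dataset",
    "save_group_dataset",
    "load_group_dataset",
    "save_records",
    "load_records",
    "write_manifest",
]


def save_sensor_dataset(
    path,
    spectra: TrialSpectra,
    leadfields: np.ndarray | None = None,
    cov: SensorCovariance | None = None,
) -> None:
    """Write sensor-level spectra (and optional forward model) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs", data=spectra.coeffs)
        f.create_dataset("freqs_hz", data=spectra.bin_frequencies)
        f.create_dataset("labels", data=np.asarray(spectra.condition_labels, float))
        if leadfields is not None:
            f.create_dataset("leadfields", data=np.asarray(leadfields, float))
        if cov is not None:
            f.create_dataset("cov", data=cov.matrix)


def load_sensor_dataset(path):
    """Inverse of :func:`save_sensor_dataset`."""
    with h5py.File(path, "r") as f:
        spectra = TrialSpectra(
            coeffs=f["coeffs"][()],
            bin_frequencies=f["freqs_hz"][()],
            condition_labels=f["labels"][()],
        )
        leadfields = f["leadfields"][()] if "leadfields" in f else None
        cov = SensorCovariance(matrix=f["cov"][()]) if "cov" in f else None
    return spectra, leadfields, cov


def save_group_dataset(path, subjects: list[SubjectSourceData], grid: VoxelGrid) -> None:
    """Write a multi-subject source-level dataset to HDF5."""
    if not subjects:
        raise ValidationError("no subjects to save")
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "voxel_ids", data=np.array(grid.voxel_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset("voxel_coords", data=grid.coords)
        f.attrs["spacing_mm"] = grid.spacing_mm
        root = f.create_group("subjects")
        for subj in subjects:
            g = root.create_group(subj.subject_id)
            g.create_dataset("coeffs", data=subj.coeffs)
            g.create_dataset("freqs_hz", data=subj.bin_frequencies)
            g.create_dataset("labels", data=np.asarray(subj.condition_labels, float))


def load_group_dataset(path) -> tuple[list[SubjectSourceData], VoxelGrid]:
    """Inverse of :func:`save_group_dataset`."""
    subjects = []
    with h5py.File(path, "r") as f:
        voxel_ids = tuple(v.decode() for v in f["voxel_ids"][()])
        grid = VoxelGrid(
            voxel_ids=voxel_ids,
            coords=f["voxel_coords"][()],
            spacing_mm=float(f.attrs["spacing_mm"]),
        )
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            subjects.append(
                SubjectSourceData(
                    subject_id=sid,
                    coeffs=g["coeffs"][()],
                    bin_frequencies=g["freqs_hz"][()],
                    condition_labels=g["labels"][()],
                    voxel_ids=voxel_ids,
                )
            )
    return subjects, grid


def save_records(path, records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"records table lacks columns {sorted(missing)}")
    records.to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"records file lacks columns {sorted(missing)}")
    return records


def write_manifest(path, config: dict, seed: int | None) -> dict:
    """Record config hash, seed and library versions next to an output.

    The manifest pins everything needed to regenerate deterministic
    outputs bit-for-bit.
    """
    import scipy

    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "cvabms": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
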