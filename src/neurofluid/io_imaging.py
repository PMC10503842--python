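"""On-disk I/O and protocol metadata for diffusion and ASL volume series.

All volumes travel as :class:`VolumeSeries` (a 4D array plus a NIfTI affine);
acquisition metadata travels as :class:`AcquisitionProtocol`.  Voxel indices
are 0-based and no reorientation is ever performed: phantom volumes, masks and
maps all live on one shared grid, with world coordinates available through the
affine.  Data are written as 32-bit float NIfTI-1; computation happens in
float64.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "VolumeSeries",
    "ASLParameters",
    "AcquisitionProtocol",
    "LabelVolume",
    "read_volume_series",
    "write_volume_series",
    "read_dwi_protocol",
    "read_asl_config",
    "write_asl_config",
    "validate_series",
]

#: unit bvec vectors closer than this are treated as the same direction
DIRECTION_TOLERANCE = 1e-6


@dataclass
class VolumeSeries:
    """A 3D voxel grid stacked along a fourth (volume) axis.

    Parameters
    ----------
    data : ndarray
        4D array of signal intensities in arbitrary scanner units.
    affine : ndarray
        4x4 voxel-to-world transform (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim} axes")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def volume(self, index: int) -> np.ndarray:
        return self.data[..., index]


@dataclass
class ASLParameters:
    """Labeling parameters for pCASL quantification.

    Defaults are the constants used for 3T choroid-plexus perfusion mapping:
    blood-brain partition coefficient lambda = 0.9 mL/g, labeling efficiency
    alpha = 0.8 (dual background suppression folded in), T1 of arterial blood
    1624 ms, label duration 1800 ms, post-label delay 2000 ms.
    """

    lambda_partition: float = 0.9
    label_efficiency_alpha: float = 0.8
    t1_blood: float = 1624.0  # ms
    label_duration_tau: float = 1800.0  # ms
    post_label_delay: float = 2000.0  # ms

    def __post_init__(self) -> None:
        for name in (
            "lambda_partition",
            "label_efficiency_alpha",
            "t1_blood",
            "label_duration_tau",
            "post_label_delay",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.label_efficiency_alpha > 1:
            raise ValueError("label_efficiency_alpha must be <= 1")


@dataclass
class AcquisitionProtocol:
    """Per-volume acquisition metadata for a DWI or ASL series.

    ``b_values`` and ``direction_index`` are per-volume; ``direction_index``
    is 0 for b=0 volumes and 1..n_dirs otherwise.  ``slice_readout_time`` is
    the per-slice delay in ms used for ASL slice-timing correction (0 disables
    the correction).
    """

    b_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    direction_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    asl_params: ASLParameters | None = None
    slice_readout_time: float = 0.0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=np.float64).ravel()
        self.direction_index = np.asarray(self.direction_index, dtype=np.int64).ravel()
        if self.b_values.size != self.direction_index.size:
            raise ValueError("b_values and direction_index must have equal length")
        if np.any(self.b_values < 0):
            raise ValueError("negative b-value")
        if np.any(self.direction_index[self.b_values == 0] != 0):
            raise ValueError("b=0 volumes must carry direction_index 0")
        if self.slice_readout_time < 0:
            raise ValueError("slice_readout_time must be >= 0")

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def shells(self) -> np.ndarray:
        """Distinct b-values, ascending."""
        return np.unique(self.b_values)


@dataclass
class LabelVolume:
    """Integer region labels on the shared grid plus a code -> name legend."""

    labels: np.ndarray
    legend: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"label codes missing from legend: {sorted(missing)}")

    def mask(self, code: int) -> np.ndarray:
        if code not in self.legend:
            raise KeyError(f"unknown region code {code}")
        return self.labels == code

    def region_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))


def read_volume_series(path: str | os.PathLike) -> VolumeSeries:
    """Read a 3D or 4D NIfTI file; 3D inputs are promoted to a single volume."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # corrupt payload, wrong magic, truncated stream
        raise ValueError(f"unreadable volume: {path}") from exc
    if data.ndim < 3:
        raise ValueError(f"expected >=3 spatial axes, got shape {data.shape}")
    if data.ndim > 4:
        raise ValueError(f"more than 4 axes in {path}")
    return VolumeSeries(data=data, affine=np.asarray(img.affine))


def write_volume_series(series: VolumeSeries, path: str | os.PathLike) -> None:
    """Write as float32 NIfTI-1; 4D with a trailing singleton is kept 4D."""
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    nib.save(img, str(path))


def write_label_volume(label: LabelVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(label.labels.astype(np.int16), label.affine)
    nib.save(img, str(path))


def read_label_volume(path: str | os.PathLike, legend: dict[int, str]) -> LabelVolume:
    series = read_volume_series(path)
    labels = np.rint(series.data[..., 0]).astype(np.int64)
    return LabelVolume(labels=labels, legend=legend, affine=series.affine)


def read_dwi_protocol(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> AcquisitionProtocol:
    """Parse FSL-style .bval/.bvec text files into an :class:`AcquisitionProtocol`.

    Direction indices are assigned by grouping identical unit vectors (within
    ``DIRECTION_TOLERANCE``); zero vectors (b=0 volumes) map to index 0.
    """
    bvals = np.loadtxt(bval_path, dtype=np.float64).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=np.float64)
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # tolerate the transposed layout
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bval length {bvals.size} does not match bvec columns {bvecs.shape[1]}"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-value in bval file")

    norms = np.sqrt((bvecs**2).sum(axis=0))
    direction_index = np.zeros(bvals.size, dtype=np.int64)
    seen: list[np.ndarray] = []
    for i in range(bvals.size):
        if bvals[i] == 0 or norms[i] == 0:
            direction_index[i] = 0
            continue
        unit = bvecs[:, i] / norms[i]
        for j, ref in enumerate(seen):
            # antipodal vectors encode the same diffusion direction
            if (np.abs(unit - ref) < DIRECTION_TOLERANCE).all() or (
                np.abs(unit + ref) < DIRECTION_TOLERANCE
            ).all():
                direction_index[i] = j + 1
                break
        else:
            seen.append(unit)
            direction_index[i] = len(seen)
    return AcquisitionProtocol(b_values=bvals, direction_index=direction_index)


def write_dwi_protocol(
    protocol: AcquisitionProtocol,
    directions: np.ndarray,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> None:
    """Write FSL-style bval/bvec text. ``directions`` is (n_dirs, 3), row d for index d+1."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in protocol.b_values) + "\n")
    vecs = np.zeros((3, protocol.n_volumes))
    for i, d in enumerate(protocol.direction_index):
        if d > 0:
            vecs[:, i] = directions[d - 1]
    with open(bvec_path, "w") as f:
        for row in vecs:
            f.write(" ".join(f"{v:.10f}" for v in row) + "\n")


def read_asl_config(path: str | os.PathLike) -> tuple[ASLParameters, float]:
    """Read ASL labeling parameters and the per-slice readout time from YAML/JSON."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    asl = ASLParameters(
        lambda_partition=float(cfg["lambda_partition"]),
        label_efficiency_alpha=float(cfg["label_efficiency_alpha"]),
        t1_blood=float(cfg["t1_blood"]),
        label_duration_tau=float(cfg["label_duration_tau"]),
        post_label_delay=float(cfg["post_label_delay"]),
    )
    return asl, float(cfg.get("slice_readout_time", 0.0))


def write_asl_config(asl: ASLParameters, slice_readout_time: float, path: str | os.PathLike) -> None:
    cfg = {
        "lambda_partition": asl.lambda_partition,
        "label_efficiency_alpha": asl.label_efficiency_alpha,
        "t1_blood": asl.t1_blood,
        "label_duration_tau": asl.label_duration_tau,
        "post_label_delay": asl.post_label_delay,
        "slice_readout_time": slice_readout_time,
    }
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f)


def validate_series(series: VolumeSeries, protocol: AcquisitionProtocol) -> list[str]:
    """Check a series/protocol pair for fit-readiness.

    Returns a report listing every violated invariant; an empty list means the
    pair can be fit.  The function is pure: neither argument is mutated.
    """
    report: list[str] = []
    if protocol.n_volumes != series.n_volumes:
        report.append(
            f"volume count mismatch: series has {series.n_volumes}, "
            f"protocol describes {protocol.n_volumes}"
        )
    if protocol.n_volumes and not np.any(protocol.b_values == 0):
        report.append("no b0 volume")
    if protocol.shells.size < 2:
        report.append("fewer than 2 distinct b-values")
    if np.any(series.data <= 0):
        report.append("nonpositive signal present")
    if not np.all(np.isfinite(series.data)):
        report.append("non-finite signal present")
    return report
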