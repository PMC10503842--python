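"""Choroid plexus perfusion quantification from pCASL control/label series.

Processing follows the standard single-post-label-delay chain: surround
subtraction of the interleaved control/label volumes, per-slice effective
post-label delay (slice-delay) correction, M0 normalization, and inversion of
the post-bolus single-compartment kinetic model

    dM / M0 = CBF * 2 alpha T1b (1 - exp(-tau/T1b)) exp(-PLD_eff/T1b) / (6000 lambda)

with CBF in mL/100 g/min, times in ms internally (T1b enters in seconds; the
6000 factor converts mL/g/s to mL/100 g/min), alpha the labeling efficiency,
lambda the blood-brain partition coefficient, tau the label duration and
PLD_eff the slice-dependent post-label delay.  The model is linear in CBF, so
the inversion is a division; the forward form doubles as the simulation and
test oracle.

A noise floor of 10 mL/100 g/min is applied after quantification: voxels
below it are never reported as quantified perfusion, and ROI summaries use
above-floor voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_imaging import ASLParameters, LabelVolume, VolumeSeries

__all__ = [
    "CBF_FLOOR",
    "PerfusionMap",
    "surround_subtract",
    "effective_pld",
    "forward_kinetic_signal",
    "quantify_cbf",
    "summarize_perfusion",
]

#: minimum quantifiable perfusion (mL/100 g/min); below it is noise floor
CBF_FLOOR = 10.0


@dataclass
class PerfusionMap:
    """Voxelwise perfusion with its noise-floor mask.

    ``cbf`` is mL/100 g/min (NaN where M0 was not positive); ``above_floor``
    marks voxels at or above :data:`CBF_FLOOR`; ``delta_m_mean`` is the
    pair-averaged label-control difference in signal units.
    """

    cbf: np.ndarray
    above_floor: np.ndarray
    delta_m_mean: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.cbf[self.above_floor] < CBF_FLOOR):
            raise ValueError("above_floor voxels must have cbf >= floor")


def surround_subtract(series: VolumeSeries) -> VolumeSeries:
    """Pairwise control-minus-label differencing with surround averaging.

    Controls sit at even volume indices, labels at odd ones.  Each label L_k
    is subtracted from the average of its neighboring controls:
    dM_k = (C_k + C_{k+1})/2 - L_k; the terminal label uses its single
    neighbor.  An odd volume count is tolerated (the trailing control is
    dropped with a warning).  Returns one dM volume per pair.
    """
    n = series.n_volumes
    if n < 2:
        raise ValueError("need at least one control/label pair")
    if n % 2 == 1:
        warnings.warn("odd volume count: dropping trailing control", stacklevel=2)
        n -= 1
    n_pairs = n // 2
    data = series.data
    dm = np.empty(series.shape3d + (n_pairs,))
    for k in range(n_pairs):
        label = data[..., 2 * k + 1]
        c_before = data[..., 2 * k]
        if 2 * k + 2 < n:
            c_after = data[..., 2 * k + 2]
            dm[..., k] = 0.5 * (c_before + c_after) - label
        else:
            dm[..., k] = c_before - label
    return VolumeSeries(data=dm, affine=series.affine.copy())


def effective_pld(
    slice_index: int, asl: ASLParameters, slice_readout_time: float
) -> float:
    """Slice-dependent post-label delay in ms for an ascending 2D readout."""
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    if slice_readout_time < 0:
        raise ValueError("slice_readout_time must be >= 0")
    return asl.post_label_delay + slice_index * slice_readout_time


def forward_kinetic_signal(
    cbf: float | np.ndarray, asl: ASLParameters, pld_eff: float | np.ndarray
) -> float | np.ndarray:
    """dM/M0 predicted by the post-bolus single-compartment model.

    ``cbf`` in mL/100 g/min, ``pld_eff`` in ms (assumed at or beyond the end
    of the labeling bolus).  Strictly increasing and linear in cbf.
    """
    if asl.t1_blood <= 0:
        raise ValueError("t1_blood must be positive")
    t1b_s = asl.t1_blood / 1000.0
    factor = (
        2.0
        * asl.label_efficiency_alpha
        * t1b_s
        * (1.0 - np.exp(-asl.label_duration_tau / asl.t1_blood))
        * np.exp(-np.asarray(pld_eff, dtype=np.float64) / asl.t1_blood)
        / (6000.0 * asl.lambda_partition)
    )
    out = np.asarray(cbf, dtype=np.float64) * factor
    return float(out) if np.isscalar(cbf) and np.isscalar(pld_eff) else out


def quantify_cbf(
    dm_series: VolumeSeries,
    m0: VolumeSeries,
    asl: ASLParameters,
    slice_readout_time: float = 0.0,
) -> PerfusionMap:
    """Invert the kinetic model voxelwise on a pair-averaged dM series.

    dM volumes are averaged over pairs, normalized by M0, and divided by the
    per-slice kinetic factor (unit-CBF forward signal at that slice's
    effective PLD).  Voxels with M0 <= 0 are unquantifiable (NaN).  The
    noise floor then marks ``above_floor = (cbf >= 10)``.
    """
    if dm_series.shape3d != m0.shape3d:
        raise ValueError("dM and M0 grids do not match")
    dm_mean = dm_series.data.mean(axis=-1)
    m0_vol = m0.volume(0)
    quantifiable = m0_vol > 0
    if not quantifiable.any():
        raise ValueError("M0 has no positive voxels")

    nz = dm_series.shape3d[2]
    pld = np.array(
        [effective_pld(k, asl, slice_readout_time) for k in range(nz)]
    )
    unit_factor = forward_kinetic_signal(1.0, asl, pld)  # dM/M0 per unit CBF

    cbf = np.full(dm_series.shape3d, np.nan)
    norm = np.zeros_like(dm_mean)
    norm[quantifiable] = dm_mean[quantifiable] / m0_vol[quantifiable]
    cbf_q = norm / unit_factor[None, None, :]
    cbf[quantifiable] = cbf_q[quantifiable]
    above = np.zeros(dm_series.shape3d, dtype=bool)
    above[quantifiable] = cbf[quantifiable] >= CBF_FLOOR
    return PerfusionMap(cbf=cbf, above_floor=above, delta_m_mean=dm_mean)


def summarize_perfusion(
    pmap: PerfusionMap, atlas: LabelVolume, region_code: int
) -> tuple[float, int]:
    """Mean perfusion over the above-floor voxels of one region.

    Returns (mean CBF in mL/100 g/min, voxel count); raises when the region
    is empty or has no quantifiable (above-floor) voxels.
    """
    region = atlas.mask(region_code)
    if not region.any():
        raise ValueError(f"region {region_code} is empty")
    sel = region & pmap.above_floor
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"no quantifiable voxels in region "
            f"{atlas.legend.get(region_code, region_code)}"
        )
    return float(pmap.cbf[sel].mean()), n
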