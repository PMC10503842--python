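"""Voxelwise exponential decay-rate mapping from multi-b diffusion MRI.

The core quantity is the decay rate ``D`` of the monoexponential model

    S(b) = S0 * exp(-b * D)

fit voxelwise over the acquired b-value shells.  Over the 0-1000 s/mm^2 range
this behaves like an apparent diffusion coefficient, but within freely
circulating CSF it reflects fluid motion (pseudo-diffusion) rather than pure
thermal diffusion, which is why it serves as a neurofluid-motion readout in
the suprasellar cistern.

Pipeline order inside :func:`fit_decay_map`: integer-voxel bulk-motion
correction -> per-shell direction combination (geometric mean; the motion is
treated as isotropic) -> nonlinear least-squares fit per voxel, initialized
from ordinary least squares on the log signal.  Voxels with fewer than three
strictly positive shell signals, or with a fitted D at or below the 1e-8
mm^2/s positivity floor, are flagged invalid rather than reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_imaging import AcquisitionProtocol, LabelVolume, VolumeSeries, validate_series

__all__ = [
    "DecayMap",
    "D_FLOOR",
    "correct_bulk_motion",
    "combine_directions",
    "fit_decay_voxel",
    "fit_decay_map",
    "summarize_roi",
]

#: fitted decay rates at or below this are flagged invalid (mm^2/s)
D_FLOOR = 1e-8

#: half-width of the integer-shift search window for motion correction (voxels)
MOTION_SEARCH = 3


@dataclass
class DecayMap:
    """Voxelwise decay-rate map with fit diagnostics.

    ``D`` (mm^2/s) and ``S0`` are NaN outside ``valid_mask``; ``r_squared``
    is computed on the untransformed signal scale; ``n_shells_used`` counts
    the strictly positive shells that entered each voxel's fit.
    """

    D: np.ndarray
    S0: np.ndarray
    r_squared: np.ndarray
    n_shells_used: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        v = self.valid_mask
        if not np.all(np.isfinite(self.D[v])) or np.any(self.D[v] <= 0):
            raise ValueError("valid voxels must have finite positive D")
        if np.any(self.n_shells_used[v] < 3):
            raise ValueError("valid voxels must use >= 3 shells")


def correct_bulk_motion(
    series: VolumeSeries, reference_index: int = 0
) -> tuple[VolumeSeries, list[tuple[int, int, int]]]:
    """Rigidly align every volume to the reference by integer-voxel translation.

    The applied shift maximizes the normalized cross-correlation with the
    reference over a +-3-voxel search window.  Shifts are circular
    (``np.roll``), under which the NCC denominator is shift-invariant, so the
    numerator alone — evaluated for all lags at once via FFT cross-correlation
    — determines the argmax.  Returns the aligned series and the per-volume
    shifts applied.
    """
    if series.n_volumes < 2:
        raise ValueError("nothing to align: series has fewer than 2 volumes")
    shape = series.shape3d
    ref = series.volume(reference_index)
    ref_c = ref - ref.mean()
    f_ref = np.fft.rfftn(ref_c)

    offsets = np.arange(-MOTION_SEARCH, MOTION_SEARCH + 1)
    aligned = np.empty_like(series.data)
    shifts: list[tuple[int, int, int]] = []
    for k in range(series.n_volumes):
        vol = series.volume(k)
        vol_c = vol - vol.mean()
        # cross[t] = sum_x ref_c[x] * vol_c[x - t]  (circular)
        cross = np.fft.irfftn(
            f_ref * np.conj(np.fft.rfftn(vol_c)), s=shape, axes=(0, 1, 2)
        )
        window = cross[np.ix_(offsets % shape[0], offsets % shape[1], offsets % shape[2])]
        if np.allclose(window, window.flat[0]):
            shift = (0, 0, 0)  # flat correlation: nothing to gain
        else:
            i, j, l = np.unravel_index(np.argmax(window), window.shape)
            shift = (int(offsets[i]), int(offsets[j]), int(offsets[l]))
        shifts.append(shift)
        aligned[..., k] = np.roll(vol, shift, axis=(0, 1, 2))
    return VolumeSeries(data=aligned, affine=series.affine.copy()), shifts


def combine_directions(
    series: VolumeSeries, protocol: AcquisitionProtocol
) -> tuple[VolumeSeries, np.ndarray]:
    """Collapse diffusion directions into one volume per distinct b-value.

    Nonzero shells are combined by the voxelwise geometric mean of their
    direction volumes (equivalent to averaging log-signals, a trace-style
    isotropic combination); b=0 volumes are averaged arithmetically.  Voxels
    with any nonpositive direction signal in a shell get 0 there, which the
    fit stage later drops.  Output shells are sorted ascending.
    """
    report = validate_series(series, protocol)
    blocking = [r for r in report if "mismatch" in r or "no b0" in r]
    if blocking:
        raise ValueError("; ".join(blocking))
    shells = protocol.shells
    out = np.empty(series.shape3d + (shells.size,))
    for s, b in enumerate(shells):
        sel = series.data[..., protocol.b_values == b]
        if sel.shape[-1] == 0:
            raise ValueError(f"shell b={b} has zero volumes")
        if b == 0:
            out[..., s] = sel.mean(axis=-1)
        else:
            ok = np.all(sel > 0, axis=-1)
            gm = np.zeros(series.shape3d)
            with np.errstate(divide="ignore", invalid="ignore"):
                gm[ok] = np.exp(np.log(sel[ok]).mean(axis=-1))
            out[..., s] = gm
    return VolumeSeries(data=out, affine=series.affine.copy()), shells


def _fit_exponential(signals: np.ndarray, b: np.ndarray, max_iter: int = 100):
    """Vectorized NLS fit of S0*exp(-b D) over rows of ``signals``.

    Rows are voxels, columns shells.  Nonpositive shells are dropped per row;
    rows with fewer than 3 usable shells are returned invalid.  Parameters
    are (log S0, D); initialization is the per-row OLS fit of log-signal on b,
    refined by damped Gauss-Newton with per-row step halving.  Returns
    (S0, D, r2, n_used, converged_mask).
    """
    signals = np.asarray(signals, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n_rows = signals.shape[0]
    use = (signals > 0) & np.isfinite(signals)
    n_used = use.sum(axis=1)
    fit = n_used >= 3

    s0 = np.full(n_rows, np.nan)
    d = np.full(n_rows, np.nan)
    r2 = np.zeros(n_rows)
    if not np.any(fit):
        return s0, d, r2, n_used, fit

    w = use[fit].astype(np.float64)
    y = np.where(use[fit], np.log(np.where(use[fit], signals[fit], 1.0)), 0.0)
    s = signals[fit]
    nsh = w.sum(axis=1)

    # log-linear OLS initializer: y = ln S0 - D b
    bw_mean = (w * b).sum(axis=1) / nsh
    yw_mean = (w * y).sum(axis=1) / nsh
    cov = (w * (b - bw_mean[:, None]) * (y - yw_mean[:, None])).sum(axis=1)
    var = (w * (b - bw_mean[:, None]) ** 2).sum(axis=1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    d_cur = np.clip(-slope, 0.0, None)
    ls0_cur = yw_mean + slope * bw_mean

    def sse(ls0, dd):
        pred = np.exp(ls0[:, None] - np.outer(dd, b))
        return (w * (pred - s) ** 2).sum(axis=1)

    cur = sse(ls0_cur, d_cur)
    for _ in range(max_iter):
        pred = np.exp(ls0_cur[:, None] - np.outer(d_cur, b))
        r = w * (pred - s)
        # Jacobian wrt (ln S0, D): (pred, -b*pred)
        j1 = w * pred
        j2 = -w * b[None, :] * pred
        a11 = (j1 * j1).sum(axis=1)
        a12 = (j1 * j2).sum(axis=1)
        a22 = (j2 * j2).sum(axis=1)
        g1 = (j1 * r).sum(axis=1)
        g2 = (j2 * r).sum(axis=1)
        det = a11 * a22 - a12**2
        ok = det > 1e-300
        step1 = np.where(ok, (a22 * g1 - a12 * g2) / np.where(ok, det, 1.0), 0.0)
        step2 = np.where(ok, (a11 * g2 - a12 * g1) / np.where(ok, det, 1.0), 0.0)
        # backtracking line search: accept the first halved step that lowers SSE
        scale = np.ones(step1.shape)
        accepted = np.zeros(step1.shape, dtype=bool)
        new_ls0, new_d = ls0_cur.copy(), d_cur.copy()
        for _ in range(25):
            pending = ~accepted
            if not pending.any():
                break
            trial_ls0 = ls0_cur - scale * step1
            trial_d = np.clip(d_cur - scale * step2, 0.0, None)
            trial = sse(trial_ls0, trial_d)
            good = pending & (trial < cur)
            new_ls0[good] = trial_ls0[good]
            new_d[good] = trial_d[good]
            cur = np.where(good, trial, cur)
            accepted |= good
            scale *= 0.5
        moved = np.abs(new_ls0 - ls0_cur) + np.abs(new_d - d_cur)
        ls0_cur, d_cur = new_ls0, new_d
        if not accepted.any() or np.max(moved) < 1e-14:
            break

    pred = np.exp(ls0_cur[:, None] - np.outer(d_cur, b))
    resid = (w * (pred - s) ** 2).sum(axis=1)
    s_mean = (w * s).sum(axis=1) / nsh
    tot = (w * (s - s_mean[:, None]) ** 2).sum(axis=1)
    r2_fit = np.where(tot > 0, 1.0 - resid / np.where(tot > 0, tot, 1.0), 0.0)

    s0[fit] = np.exp(ls0_cur)
    d[fit] = d_cur
    r2[fit] = np.clip(r2_fit, 0.0, 1.0)
    valid = fit.copy()
    valid[fit] &= d_cur > D_FLOOR
    return s0, d, r2, n_used, valid


def fit_decay_voxel(
    shell_signals: np.ndarray, shell_bvalues: np.ndarray
) -> tuple[float, float, float, int]:
    """Fit S0*exp(-b D) to one voxel's per-shell signals.

    Returns (S0, D, r2, n_shells_used); S0 and D are NaN when fewer than
    three shells carry strictly positive signal or the fit lands at the
    D positivity floor.
    """
    signals = np.asarray(shell_signals, dtype=np.float64).reshape(1, -1)
    b = np.asarray(shell_bvalues, dtype=np.float64).ravel()
    if signals.shape[1] != b.size:
        raise ValueError("shell_signals and shell_bvalues must have equal length")
    s0, d, r2, n_used, valid = _fit_exponential(signals, b)
    if not valid[0]:
        return float("nan"), float("nan"), float(r2[0]), int(n_used[0])
    return float(s0[0]), float(d[0]), float(r2[0]), int(n_used[0])


def fit_decay_map(
    series: VolumeSeries,
    protocol: AcquisitionProtocol,
    mask: LabelVolume | np.ndarray | None = None,
    motion_correct: bool = True,
) -> DecayMap:
    """Full decay-mapping pipeline over the masked voxels of a DWI series.

    ``mask`` may be a boolean array, a :class:`LabelVolume` (every nonzero
    region is fit), or None (all voxels).  Unmasked voxels are invalid in the
    output.
    """
    if isinstance(mask, LabelVolume):
        mask_arr = mask.labels > 0
    elif mask is None:
        mask_arr = np.ones(series.shape3d, dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    if mask_arr.shape != series.shape3d:
        raise ValueError(
            f"mask grid {mask_arr.shape} does not match series grid {series.shape3d}"
        )

    if motion_correct and series.n_volumes >= 2:
        b0_idx = int(np.flatnonzero(protocol.b_values == 0)[0])
        series, _ = correct_bulk_motion(series, reference_index=b0_idx)
    combined, shells = combine_directions(series, protocol)

    shape = series.shape3d
    flat = combined.data.reshape(-1, shells.size)[mask_arr.ravel()]
    s0, d, r2, n_used, valid = _fit_exponential(flat, shells)

    def unflatten(vec, fill, dtype=np.float64):
        out = np.full(shape, fill, dtype=dtype)
        out.reshape(-1)[mask_arr.ravel()] = vec
        return out

    return DecayMap(
        D=unflatten(np.where(valid, d, np.nan), np.nan),
        S0=unflatten(np.where(valid, s0, np.nan), np.nan),
        r_squared=unflatten(r2, 0.0),
        n_shells_used=unflatten(n_used, 0, dtype=np.int64),
        valid_mask=unflatten(valid, False, dtype=bool),
    )


def summarize_roi(
    dmap: DecayMap, atlas: LabelVolume, region_code: int
) -> tuple[float, int]:
    """Mean decay rate over the valid voxels of one atlas region.

    Returns (mean D in mm^2/s, number of voxels used); raises if the region
    has no valid voxels.
    """
    region = atlas.mask(region_code)
    sel = region & dmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"region {atlas.legend.get(region_code, region_code)} has no valid voxels"
        )
    return float(dmap.D[sel].mean()), n
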