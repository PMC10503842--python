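"""Digital phantoms and synthetic cohorts for the neurofluid pipeline.

The study this package reproduces measured cerebrospinal-fluid (CSF) motion
(an exponential decay rate of the DWI signal over b-values) and choroid plexus
perfusion (pCASL) in Parkinson's disease (PD) and healthy older adults; its
raw images are not deposited, so everything downstream is exercised on
phantoms generated here.

Two levels are provided:

* **image level** — a blocky tissue atlas (white matter core, gray matter
  shell, two lateral-ventricle CSF blocks each containing a choroid-plexus
  sub-block, and a small midline inferior suprasellar-cistern CSF region) and
  forward simulators for the multi-b DWI signal ``S(b) = S0 exp(-b D)`` and
  for interleaved pCASL control/label pairs driven by the single-compartment
  kinetic model.  DWI magnitude noise is Rician; ASL volumes get Gaussian
  noise (subtraction-regime statistics).  One ``snr`` number controls both,
  referenced to the white-matter S0.

* **cohort level** — per-subject ROI summaries drawn from the published group
  means/SDs, with the PD-only inverse perfusion-decay association injected
  through a Gaussian copula calibrated by rho = 2 sin(pi rho_s / 6).

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_imaging import AcquisitionProtocol, ASLParameters, LabelVolume, VolumeSeries

__all__ = [
    "BACKGROUND",
    "WM",
    "GM",
    "VENTRICLE_CSF",
    "SUPRASELLAR",
    "CHOROID_PLEXUS",
    "REGION_LEGEND",
    "TissueParameters",
    "CohortSpec",
    "default_dwi_protocol",
    "build_tissue_atlas",
    "simulate_dwi_series",
    "simulate_asl_series",
    "pearson_from_spearman",
    "sample_rank_correlated_pairs",
    "simulate_cohort",
]

BACKGROUND = 0
WM = 1
GM = 2
VENTRICLE_CSF = 3
SUPRASELLAR = 4
CHOROID_PLEXUS = 5

REGION_LEGEND: dict[int, str] = {
    BACKGROUND: "background",
    WM: "white_matter",
    GM: "gray_matter",
    VENTRICLE_CSF: "ventricle_csf",
    SUPRASELLAR: "suprasellar_cistern",
    CHOROID_PLEXUS: "choroid_plexus",
}

#: decay rates below this are considered nonphysical when drawing cohorts (mm^2/s)
DECAY_FLOOR = 1e-5

#: the seven-shell protocol: b-values in s/mm^2, cycled over 6 directions
PROTOCOL_B_VALUES = (0.0, 50.0, 100.0, 200.0, 300.0, 700.0, 1000.0)

# a standard 6-direction DTI scheme (unit vectors)
_SIX_DIRECTIONS = np.array(
    [
        [1, 0, 1],
        [-1, 0, 1],
        [0, 1, 1],
        [0, 1, -1],
        [1, 1, 0],
        [-1, 1, 0],
    ],
    dtype=np.float64,
)
_SIX_DIRECTIONS /= np.sqrt((_SIX_DIRECTIONS**2).sum(axis=1, keepdims=True))


@dataclass
class TissueParameters:
    """Ground-truth tissue properties per atlas region.

    Decay-rate defaults are the healthy-cohort group means (mm^2/s): white
    matter 0.00131, gray matter 0.00138, ventricular CSF 0.00241, suprasellar
    cistern 0.00328.  The choroid plexus, a vascularized tissue inside the
    ventricle, is given a GM-like decay rate and the healthy-mean perfusion of
    31.3 mL/100 g/min; all other regions have zero perfusion.  S0 values are
    arbitrary scanner units with CSF brightest, roughly echoing long-TE
    diffusion EPI contrast.
    """

    decay: dict[int, float] = field(
        default_factory=lambda: {
            WM: 0.00131,
            GM: 0.00138,
            VENTRICLE_CSF: 0.00241,
            SUPRASELLAR: 0.00328,
            CHOROID_PLEXUS: 0.00140,
        }
    )
    s0: dict[int, float] = field(
        default_factory=lambda: {
            WM: 700.0,
            GM: 800.0,
            VENTRICLE_CSF: 1000.0,
            SUPRASELLAR: 1000.0,
            CHOROID_PLEXUS: 850.0,
        }
    )
    perfusion: dict[int, float] = field(
        default_factory=lambda: {CHOROID_PLEXUS: 31.3}
    )

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.decay.values()):
            raise ValueError("decay rates must be strictly positive")
        if any(s <= 0 for s in self.s0.values()):
            raise ValueError("S0 values must be strictly positive")

    def decay_map(self, atlas: LabelVolume) -> np.ndarray:
        return self._paint(atlas, self.decay)

    def s0_map(self, atlas: LabelVolume) -> np.ndarray:
        return self._paint(atlas, self.s0)

    def perfusion_map(self, atlas: LabelVolume) -> np.ndarray:
        out = np.zeros(atlas.labels.shape)
        for code, f in self.perfusion.items():
            out[atlas.labels == code] = f
        return out

    def _paint(self, atlas: LabelVolume, values: dict[int, float]) -> np.ndarray:
        missing = [
            c for c in atlas.region_codes() if c != BACKGROUND and c not in values
        ]
        if missing:
            raise ValueError(f"atlas regions missing from parameters: {missing}")
        out = np.zeros(atlas.labels.shape)
        for code, v in values.items():
            out[atlas.labels == code] = v
        return out


def default_dwi_protocol() -> AcquisitionProtocol:
    """The seven-shell cycling protocol: one leading b0 then 6 directions per shell.

    7 b-values x 6 directions + 1 b0 = 43 volumes; b=0 repeats carry
    direction index 0.
    """
    b_values = [0.0]
    direction_index = [0]
    for b in PROTOCOL_B_VALUES:
        for d in range(6):
            b_values.append(b)
            direction_index.append(0 if b == 0 else d + 1)
    return AcquisitionProtocol(
        b_values=np.array(b_values), direction_index=np.array(direction_index)
    )


def protocol_directions() -> np.ndarray:
    """The (6, 3) unit direction set matching ``default_dwi_protocol`` indices."""
    return _SIX_DIRECTIONS.copy()


def build_tissue_atlas(
    dims: tuple[int, int, int] = (64, 64, 28), seed: int = 0
) -> LabelVolume:
    """Construct a blocky tissue atlas on the given grid.

    Deterministic given (dims, seed): the seed jitters region centers by up to
    one voxel.  Raises if any dimension is below 16 (the regions no longer
    fit).
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 16 for d in dims):
        raise ValueError(f"each dimension must be >= 16, got {dims}")
    rng = np.random.default_rng(seed)
    jitter = rng.integers(-1, 2, size=3)

    nx, ny, nz = dims
    labels = np.zeros(dims, dtype=np.int64)
    cx, cy, cz = (
        nx // 2 + int(jitter[0]),
        ny // 2 + int(jitter[1]),
        nz // 2 + int(jitter[2]),
    )

    # head: ellipsoid of GM enclosing a WM ellipsoid core
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    rx, ry, rz = 0.45 * nx, 0.45 * ny, 0.45 * nz
    head = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
    core = (
        ((x - cx) / (0.7 * rx)) ** 2
        + ((y - cy) / (0.7 * ry)) ** 2
        + ((z - cz) / (0.7 * rz)) ** 2
        <= 1.0
    )
    labels[head] = GM
    labels[core] = WM

    def _box(x0, x1, y0, y1, z0, z1, code):
        labels[x0:x1, y0:y1, z0:z1] = code

    # two lateral-ventricle CSF blocks flanking the midline, each holding a
    # choroid-plexus sub-block
    vx = max(5, nx // 10)
    vy = max(6, ny // 6)
    vz = max(4, nz // 5)
    zv0 = cz - vz // 2
    for side in (-1, 1):
        x0 = cx + side * max(2, nx // 12) - (vx if side < 0 else 0)
        x1 = x0 + vx
        y0 = cy - vy // 2
        _box(x0, x1, y0, y0 + vy, zv0, zv0 + vz, VENTRICLE_CSF)
        # choroid plexus occupies the posterior third of each ventricle block
        px = max(3, vx // 2)
        py = max(3, vy // 3)
        pz = max(3, vz - 1)
        _box(
            x0 + (vx - px) // 2,
            x0 + (vx - px) // 2 + px,
            y0 + vy - py,
            y0 + vy,
            zv0,
            zv0 + pz,
            CHOROID_PLEXUS,
        )

    # small midline suprasellar-cistern region, inferior (low z)
    sx = max(3, nx // 12)
    sy = max(3, ny // 12)
    sz = max(3, nz // 8)
    z0 = max(1, cz - max(2, int(round(rz))) // 2 - sz // 2)
    _box(cx - sx // 2, cx - sx // 2 + sx, cy - sy // 2, cy - sy // 2 + sy, z0, z0 + sz, SUPRASELLAR)

    atlas = LabelVolume(labels=labels, legend=REGION_LEGEND)
    for code in (WM, GM, VENTRICLE_CSF, SUPRASELLAR, CHOROID_PLEXUS):
        n = int(atlas.mask(code).sum())
        if n < 20:
            raise ValueError(
                f"dims {dims} too small: region {REGION_LEGEND[code]} has {n} voxels"
            )
    return atlas


def simulate_dwi_series(
    atlas: LabelVolume,
    params: TissueParameters,
    protocol: AcquisitionProtocol,
    snr: float | None = None,
    seed: int = 0,
) -> VolumeSeries:
    """Forward-simulate the multi-b DWI series S(b) = S0 exp(-b D).

    Motion is isotropic: every direction at one b-value shares the same
    noiseless signal.  With ``snr`` set, each volume is corrupted with Rician
    noise sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma), sigma = S0(WM)/snr.
    """
    if protocol.shells.size < 2 or 0.0 not in protocol.shells:
        raise ValueError("protocol needs >= 2 distinct b-values including 0")
    d_map = params.decay_map(atlas)
    s0_map = params.s0_map(atlas)
    signal = s0_map[..., None] * np.exp(
        -np.multiply.outer(d_map, protocol.b_values)
    )
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        sigma = params.s0[WM] / snr
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return VolumeSeries(data=signal, affine=atlas.affine)


def simulate_asl_series(
    atlas: LabelVolume,
    params: TissueParameters,
    asl: ASLParameters,
    n_pairs: int = 10,
    snr: float | None = None,
    seed: int = 0,
    slice_readout_time: float = 0.0,
) -> tuple[VolumeSeries, VolumeSeries]:
    """Forward-simulate interleaved pCASL control/label pairs plus an M0 volume.

    Control volumes equal the tissue M0 (taken as the S0 map); label volumes
    are control - dM with dM = forward_kinetic_signal(f_true) * M0 in perfused
    regions, using each slice's effective post-label delay.  Controls sit at
    even volume indices.  With ``snr`` set, Gaussian noise with
    sigma = M0(WM)/snr is added to every control/label volume.
    """
    from .asl import forward_kinetic_signal  # local import to avoid a cycle

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    m0_map = params.s0_map(atlas)
    f_map = params.perfusion_map(atlas)
    nz = atlas.labels.shape[2]
    pld_eff = asl.post_label_delay + np.arange(nz) * float(slice_readout_time)
    dm_frac = forward_kinetic_signal(f_map, asl, pld_eff[None, None, :])
    dm = dm_frac * m0_map
    control = m0_map
    label = control - dm

    vols = np.empty(atlas.labels.shape + (2 * n_pairs,))
    vols[..., 0::2] = control[..., None]
    vols[..., 1::2] = label[..., None]
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        sigma = params.s0[WM] / snr
        rng = np.random.default_rng(seed)
        vols = vols + rng.normal(0.0, sigma, size=vols.shape)
    series = VolumeSeries(data=vols, affine=atlas.affine)
    m0 = VolumeSeries(data=m0_map[..., None], affine=atlas.affine)
    return series, m0


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------


def pearson_from_spearman(rho_s: float) -> float:
    """Pearson parameter of a Gaussian copula with target Spearman rho_s.

    Inverts the bivariate-normal rank-correlation identity
    rho_s = (6/pi) asin(rho/2), i.e. rho = 2 sin(pi rho_s / 6).
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("rank correlation must lie in [-1, 1]")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def sample_rank_correlated_pairs(
    rho_s: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n, 2) standard-normal pairs whose population Spearman is rho_s."""
    rho = pearson_from_spearman(rho_s)
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    return z


@dataclass
class CohortSpec:
    """Statistical structure of the synthetic cohort.

    Defaults reproduce the published group summaries: 32 healthy / 27 PD
    subjects; per-ROI decay-rate means +- SD per group; choroid plexus
    perfusion 31.3 +- 5.6 (healthy) vs 31.5 +- 7.9 (PD) mL/100 g/min; a
    perfusion-decay Spearman correlation of -0.51 injected in the PD group
    only (the healthy association was a null result, taken as 0); ages
    67.6 +- 9.0 vs 66.0 +- 6.8 years; UPDRS 32.4 +- 12.5 in PD; MoCA
    26.5 +- 2.8 vs 24.3 +- 3.9.  Sex ratio defaults to 0.5 per group.
    """

    n_per_group: tuple[int, int] = (32, 27)  # (healthy, PD)
    decay_healthy: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wm_d": (0.00131, 0.00026),
            "gm_d": (0.00138, 0.00026),
            "ventricle_d": (0.00241, 0.00035),
            "suprasellar_d": (0.00328, 0.00123),
        }
    )
    decay_pd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wm_d": (0.00129, 0.00023),
            "gm_d": (0.00136, 0.00024),
            "ventricle_d": (0.00239, 0.00033),
            "suprasellar_d": (0.00256, 0.00094),
        }
    )
    perfusion_healthy: tuple[float, float] = (31.3, 5.6)
    perfusion_pd: tuple[float, float] = (31.5, 7.9)
    rho_s_pd: float = -0.51
    rho_s_healthy: float = 0.0
    age_healthy: tuple[float, float] = (67.6, 9.0)
    age_pd: tuple[float, float] = (66.0, 6.8)
    sex_ratio: float = 0.5  # fraction female in each group
    updrs_pd: tuple[float, float] = (32.4, 12.5)
    moca_healthy: tuple[float, float] = (26.5, 2.8)
    moca_pd: tuple[float, float] = (24.3, 3.9)
    rho_s_updrs: float = 0.0  # optional UPDRS-decay rank correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs >= 2 subjects")
        for rho in (self.rho_s_pd, self.rho_s_healthy, self.rho_s_updrs):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("rank correlations must lie in [-1, 1]")
        for d in (self.decay_healthy, self.decay_pd):
            if any(sd < 0 for _, sd in d.values()):
                raise ValueError("SDs must be >= 0")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-subject cohort table with the statistical structure of ``spec``.

    Decay rates and perfusion are Normal(mean, SD) per group, floored at
    ``DECAY_FLOOR`` (decay) / 0.1 mL/100 g/min (perfusion).  Within each
    group, suprasellar decay and choroid plexus perfusion are drawn jointly
    from a Gaussian copula calibrated to the group's target Spearman
    correlation; in PD, UPDRS can optionally be rank-correlated with the
    suprasellar decay the same way.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, n, decay_spec, perf_spec, age_spec, moca_spec, rho_s in (
        ("healthy", spec.n_per_group[0], spec.decay_healthy, spec.perfusion_healthy,
         spec.age_healthy, spec.moca_healthy, spec.rho_s_healthy),
        ("PD", spec.n_per_group[1], spec.decay_pd, spec.perfusion_pd,
         spec.age_pd, spec.moca_pd, spec.rho_s_pd),
    ):
        z = sample_rank_correlated_pairs(rho_s, n, rng)
        sup_mean, sup_sd = decay_spec["suprasellar_d"]
        sup = np.maximum(sup_mean + sup_sd * z[:, 0], DECAY_FLOOR)
        perf = np.maximum(perf_spec[0] + perf_spec[1] * z[:, 1], 0.1)
        other = {
            k: np.maximum(m + s * rng.standard_normal(n), DECAY_FLOOR)
            for k, (m, s) in decay_spec.items()
            if k != "suprasellar_d"
        }
        age = age_spec[0] + age_spec[1] * rng.standard_normal(n)
        sex = np.where(rng.random(n) < spec.sex_ratio, "F", "M")
        moca = moca_spec[0] + moca_spec[1] * rng.standard_normal(n)
        if group == "PD":
            # rank-correlate UPDRS with suprasellar decay through the copula
            zu = pearson_from_spearman(spec.rho_s_updrs) * z[:, 0]
            zu = zu + np.sqrt(1 - pearson_from_spearman(spec.rho_s_updrs) ** 2) * rng.standard_normal(n)
            updrs = spec.updrs_pd[0] + spec.updrs_pd[1] * zu
        else:
            updrs = np.full(n, np.nan)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{sid:03d}",
                    "group": group,
                    "age": age[i],
                    "sex": sex[i],
                    "wm_d": other["wm_d"][i],
                    "gm_d": other["gm_d"][i],
                    "ventricle_d": other["ventricle_d"][i],
                    "suprasellar_d": sup[i],
                    "cp_perfusion": perf[i],
                    "updrs": updrs[i],
                    "moca": moca[i],
                }
            )
            sid += 1
    return pd.DataFrame(rows)
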