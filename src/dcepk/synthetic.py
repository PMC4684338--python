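"""Synthetic DCE-MRI phantoms and simulated patient cohorts.

Two generators cover the two scales of the analysis:

* :func:`generate_phantom` builds a 4D dynamic SPGR magnitude series from
  known ground truth — tissue regions driven by Tofts kinetics with a
  parametric population AIF, an artery region carrying the blood signal, a
  low-flip-angle pre-contrast volume for T1 mapping, and reproducible noise.
  Every downstream stage (relaxometry, concentration conversion, AIF
  extraction, model fitting, ROI statistics) can be validated against the
  truth without any acquired data.

* :func:`generate_cohort` draws per-site parameter values from per-group
  normal distributions (site control vs site failure), so the statistical
  layer can be exercised on cohorts whose group means and SDs match a stated
  table of moments.

A parametric AIF replaces manual arterial voxel selection: it is
reproducible and has closed-form integrals that serve as oracles. The
default is a biexponential decay with a linear upslope; a pure biexponential
and a Parker-type mixture are also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, RelaxivityConstants, DEFAULT_HEMATOCRIT
from .relaxometry import spgr_signal
from .kinetics import tofts_forward

__all__ = [
    "AIFModelParams",
    "TissueRegion",
    "ArteryRegion",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "DEFAULT_AIF",
    "evaluate_aif",
    "synthesize_signal",
    "snr_to_sigma",
    "generate_phantom",
    "generate_cohort",
    "default_phantom_spec",
    "residual_mass_cohort_spec",
]


@dataclass(frozen=True)
class AIFModelParams:
    """Parametric population arterial input function.

    ``model_name`` selects the functional form ("biexponential",
    "biexponential_upslope", "parker"); ``parameters`` holds its named
    scalars (amplitudes in mM, rates in min⁻¹, times in seconds);
    ``onset_time`` is the bolus arrival in seconds from the start of the
    dynamic series.
    """

    model_name: str
    parameters: dict
    onset_time: float = 12.0


#: Default population AIF: linear upslope over 8 s to peak, then
#: biexponential washout. Amplitudes chosen so a tissue curve at typical
#: head-and-neck tumor kinetics (Ktrans ≈ 0.37 min⁻¹, kep ≈ 0.67 min⁻¹)
#: integrates to ≈ 2.4 mM·min over the default acquisition.
DEFAULT_AIF = AIFModelParams(
    model_name="biexponential_upslope",
    parameters={"a1": 1.4, "m1": 1.0, "a2": 0.55, "m2": 0.05, "rise_time": 8.0},
    onset_time=12.0,
)

#: Parker-type population AIF (two Gaussian first-pass peaks plus a
#: sigmoid-gated exponential washout); times internal to the model are in
#: minutes after onset.
PARKER_DEFAULTS = {
    "A1": 0.809, "T1": 0.17046, "sigma1": 0.0563,
    "A2": 0.330, "T2": 0.365, "sigma2": 0.132,
    "alpha": 1.050, "beta": 0.1685, "s": 38.078, "tau": 0.483,
}


def evaluate_aif(params: AIFModelParams, t_grid) -> np.ndarray:
    """Evaluate the plasma concentration C_p(t) of a parametric AIF.

    ``t_grid`` is in seconds and must be strictly increasing; the curve is
    zero before ``params.onset_time`` and nonnegative everywhere.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    p = params.parameters
    tau_min = (t - params.onset_time) / 60.0       # minutes since onset
    cp = np.zeros_like(t)

    if params.model_name == "biexponential":
        m = tau_min >= 0
        cp[m] = p["a1"] * np.exp(-p["m1"] * tau_min[m]) + p["a2"] * np.exp(
            -p["m2"] * tau_min[m]
        )
    elif params.model_name == "biexponential_upslope":
        rise = p["rise_time"] / 60.0
        peak = p["a1"] + p["a2"]
        up = (tau_min >= 0) & (tau_min < rise)
        cp[up] = peak * tau_min[up] / rise
        dn = tau_min >= rise
        td = tau_min[dn] - rise
        cp[dn] = p["a1"] * np.exp(-p["m1"] * td) + p["a2"] * np.exp(-p["m2"] * td)
    elif params.model_name == "parker":
        q = {**PARKER_DEFAULTS, **p}
        m = tau_min >= 0
        tm = tau_min[m]
        gauss = sum(
            q[A] / (q[s] * np.sqrt(2 * np.pi))
            * np.exp(-((tm - q[T]) ** 2) / (2 * q[s] ** 2))
            for A, T, s in (("A1", "T1", "sigma1"), ("A2", "T2", "sigma2"))
        )
        washout = q["alpha"] * np.exp(-q["beta"] * tm) / (
            1 + np.exp(-q["s"] * (tm - q["tau"]))
        )
        cp[m] = gauss + washout
    else:
        raise ValueError(f"unknown AIF model {params.model_name!r}")
    return cp


def aif_integral_biexponential(params: AIFModelParams) -> float:
    """Closed-form ∫₀^∞ C_p dt (mM·min) for the pure biexponential model."""
    if params.model_name != "biexponential":
        raise ValueError("closed-form integral defined for 'biexponential' only")
    p = params.parameters
    return p["a1"] / p["m1"] + p["a2"] / p["m2"]


def snr_to_sigma(snr: float, t10: float, m0: float,
                 protocol: AcquisitionProtocol) -> float:
    """Noise SD giving the requested SNR on the pre-contrast dynamic signal."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(spgr_signal(m0, t10, protocol.flip_dynamic, protocol.tr)) / snr


def synthesize_signal(
    ct,
    t10: float,
    m0: float,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    constants: RelaxivityConstants = RelaxivityConstants(),
    flip: Optional[float] = None,
    noise_model: str = "gaussian",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """SPGR magnitude signal for a tissue concentration curve.

    Applies R1(t) = 1/T10 + r1·C(t) through the SPGR equation at the dynamic
    flip angle (or ``flip`` if given) and adds reproducible noise. Frames
    where C = 0 (the pre-injection baseline) carry the plain SPGR signal at
    T10. Noise models: additive "gaussian" (default) or "rician"
    (magnitude of the complex signal with Gaussian noise on both channels).
    """
    ct = np.asarray(ct, dtype=float)
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    if np.any(ct < -1e-12):
        raise ValueError("ct must be nonnegative")
    alpha = protocol.flip_dynamic if flip is None else flip
    r1t = 1.0 / t10 + constants.r1 * ct / 1000.0    # ms⁻¹
    sig = spgr_signal(m0, 1.0 / r1t, alpha, protocol.tr)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            sig = sig + rng.normal(0.0, noise_sigma, sig.shape)
        elif noise_model == "rician":
            sig = np.hypot(
                sig + rng.normal(0.0, noise_sigma, sig.shape),
                rng.normal(0.0, noise_sigma, sig.shape),
            )
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return sig


@dataclass(frozen=True)
class TissueRegion:
    """Homogeneous tissue region with known Tofts kinetics."""

    name: str
    mask: np.ndarray
    ktrans: float               # min⁻¹
    kep: float                  # min⁻¹
    t1: float                   # ms
    m0: float

    def __post_init__(self) -> None:
        if self.ktrans <= 0 or self.kep <= 0:
            raise ValueError(f"region {self.name}: ktrans and kep must be positive")
        if self.ktrans / self.kep > 1.0:
            raise ValueError(
                f"region {self.name}: ve = ktrans/kep = "
                f"{self.ktrans / self.kep:.3f} exceeds 1"
            )
        if self.t1 <= 0 or self.m0 <= 0:
            raise ValueError(f"region {self.name}: t1 and m0 must be positive")


@dataclass(frozen=True)
class ArteryRegion:
    """Artery voxels carrying the blood signal C_b = C_p · (1 − Hct)."""

    mask: np.ndarray
    t1: float = 1650.0          # blood T1 at 3 T (ms)
    m0: float = 1000.0


@dataclass
class PhantomSpec:
    """Geometry, ground truth and noise level of a digital DCE phantom."""

    grid_shape: tuple[int, int, int]
    tissue_regions: list[TissueRegion]
    artery_region: ArteryRegion
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        occupancy = np.zeros(self.grid_shape, dtype=int)
        for reg in self.tissue_regions:
            if reg.mask.shape != self.grid_shape:
                raise ValueError(f"region {reg.name}: mask shape mismatch")
            occupancy += reg.mask.astype(int)
        if self.artery_region.mask.shape != self.grid_shape:
            raise ValueError("artery mask shape mismatch")
        occupancy += self.artery_region.mask.astype(int)
        if occupancy.max() > 1:
            raise ValueError("phantom region masks overlap")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class Phantom:
    """A generated phantom: dynamic series, masks and ground truth."""

    signal: np.ndarray                 # X×Y×Z×T dynamic series at flip_dynamic
    flip_low: np.ndarray               # X×Y×Z pre-contrast volume at flip_t1map
    masks: dict                        # region name -> bool mask
    artery_mask: np.ndarray
    truth: dict                        # 'ktrans','kep','ve','t1','m0' maps
    cp: np.ndarray                     # true plasma concentration (mM)
    t_grid: np.ndarray                 # seconds
    protocol: AcquisitionProtocol
    hematocrit: float


def generate_phantom(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    aif: AIFModelParams = DEFAULT_AIF,
    constants: RelaxivityConstants = RelaxivityConstants(),
    hematocrit: float = DEFAULT_HEMATOCRIT,
) -> Phantom:
    """Build a 4D dynamic series with known kinetics.

    Tissue voxels follow ``tofts_forward`` of their region's ground truth
    driven by the parametric AIF; artery voxels carry the whole-blood
    concentration C_b = C_p · (1 − Hct). A matching low-flip-angle
    pre-contrast volume is produced for dual-angle T1 mapping. All noise
    derives from ``spec.seed``.
    """
    t = protocol.t_grid()
    cp = evaluate_aif(aif, t)
    if aif.onset_time < protocol.injection_start:
        raise ValueError("AIF onset precedes the injection command")
    rng = np.random.default_rng(spec.seed)

    shape = spec.grid_shape
    signal = np.zeros(shape + (t.size,))
    flip_low = np.zeros(shape)
    truth = {k: np.full(shape, np.nan) for k in ("ktrans", "kep", "ve", "t1", "m0")}
    masks = {}

    def fill(mask, ct_curve, t1, m0):
        sig = synthesize_signal(ct_curve, t1, m0, protocol, constants=constants)
        signal[mask] = sig
        flip_low[mask] = spgr_signal(m0, t1, protocol.flip_t1map, protocol.tr)
        truth["t1"][mask] = t1
        truth["m0"][mask] = m0

    for reg in spec.tissue_regions:
        ct_curve = tofts_forward(reg.ktrans, reg.kep, cp, t)
        fill(reg.mask, ct_curve, reg.t1, reg.m0)
        truth["ktrans"][reg.mask] = reg.ktrans
        truth["kep"][reg.mask] = reg.kep
        truth["ve"][reg.mask] = reg.ktrans / reg.kep
        masks[reg.name] = reg.mask.astype(bool)

    art = spec.artery_region
    cb = cp * (1.0 - hematocrit)
    fill(art.mask, cb, art.t1, art.m0)

    # background: weakly relaxing tissue with no enhancement
    covered = np.zeros(shape, dtype=bool)
    for m in masks.values():
        covered |= m
    covered |= art.mask.astype(bool)
    bg = ~covered
    fill(bg, np.zeros_like(t), 900.0, 800.0)

    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
        flip_low = flip_low + rng.normal(0.0, spec.noise_sigma, flip_low.shape)

    return Phantom(
        signal=signal,
        flip_low=flip_low,
        masks=masks,
        artery_mask=art.mask.astype(bool),
        truth=truth,
        cp=cp,
        t_grid=t,
        protocol=protocol,
        hematocrit=hematocrit,
    )


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = (10, 10, 4),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Two tumor-like tissue regions plus a small artery column.

    Region kinetics sit at typical head-and-neck SCC values (Ktrans
    0.37/0.33 min⁻¹, kep 0.67/0.64 min⁻¹) with tissue T1 ≈ 1100 ms and
    blood T1 1650 ms at 3 T.
    """
    x, y, z = grid_shape
    m_a = np.zeros(grid_shape, dtype=bool)
    m_b = np.zeros(grid_shape, dtype=bool)
    m_art = np.zeros(grid_shape, dtype=bool)
    m_a[2 : x // 2, 2 : y - 2, :] = True
    m_b[x // 2 + 1 : x - 2, 2 : y - 2, :] = True
    # two carotid-like vessel columns, 2×2 in plane through all slices
    m_art[:2, :2, :] = True
    m_art[x - 2 :, y - 2 :, :] = True
    return PhantomSpec(
        grid_shape=grid_shape,
        tissue_regions=[
            TissueRegion("tumor_a", m_a, ktrans=0.37, kep=0.67, t1=1100.0, m0=1000.0),
            TissueRegion("tumor_b", m_b, ktrans=0.33, kep=0.64, t1=1000.0, m0=1000.0),
        ],
        artery_region=ArteryRegion(mask=m_art),
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class CohortSpec:
    """Per-group normal moments for simulated per-site parameter values.

    ``params`` maps parameter name -> {group: (mean, sd)}; ``group_sizes``
    maps group label (e.g. "SF", "SC") -> n; ``primary_fraction`` sets the
    share of primary (vs nodal) sites per group.
    """

    group_sizes: dict
    params: dict
    primary_fraction: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g}: size must be positive")
        for name, groups in self.params.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"{name}/{g}: SD must be nonnegative")


def residual_mass_cohort_spec(
    n_sf: int = 14, n_sc: int = 19, seed: int = 0
) -> CohortSpec:
    """Moments of the post-treatment residual-mass cohort (site failure vs
    site control): per-group means and SDs of the DCE parameters, their
    percentage changes from pre-treatment, and volume."""
    p = {
        "ktrans":            {"SF": (0.35, 0.14),   "SC": (0.26, 0.16)},
        "pct_change_ktrans": {"SF": (16.09, 71.80), "SC": (-20.32, 50.93)},
        "kep":               {"SF": (0.52, 0.23),   "SC": (0.35, 0.23)},
        "pct_change_kep":    {"SF": (-15.90, 52.43), "SC": (-34.27, 53.75)},
        "ve":                {"SF": (0.75, 0.18),   "SC": (0.83, 0.26)},
        "pct_change_ve":     {"SF": (53.10, 48.48), "SC": (55.46, 90.80)},
        "augc":              {"SF": (3.00, 1.06),   "SC": (2.11, 0.89)},
        "pct_change_augc":   {"SF": (42.64, 64.83), "SC": (-12.63, 39.86)},
        "volume":            {"SF": (1.47, 2.71),   "SC": (0.83, 0.66)},
        "pct_change_volume": {"SF": (-0.68, 0.22),  "SC": (-0.74, 0.16)},
    }
    return CohortSpec(
        group_sizes={"SF": n_sf, "SC": n_sc},
        params=p,
        primary_fraction={"SF": 7 / 14, "SC": 12 / 19},
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-site cohort table from the group moments.

    Returns a DataFrame with columns site_id, site_type, outcome and one
    column per parameter; values are independent normal draws with the
    group's mean and SD. Sample moments converge to the spec moments as the
    group sizes grow, and a fixed seed reproduces the cohort exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        frac = spec.primary_fraction.get(group, 0.5)
        n_primary = int(round(frac * n))
        for i in range(n):
            rows.append(
                {
                    "site_id": f"{group}_{i:03d}",
                    "site_type": "primary" if i < n_primary else "nodal",
                    "outcome": group,
                }
            )
    df = pd.DataFrame(rows)
    for name in spec.params:
        vals = np.empty(len(df))
        for group in sorted(spec.group_sizes):
            mean, sd = spec.params[name][group]
            sel = (df["outcome"] == group).to_numpy()
            vals[sel] = rng.normal(mean, sd, sel.sum()) if sd > 0 else mean
        df[name] = vals
    return df
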