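"""Tracer kinetics: signal↔concentration conversion, AIF, Tofts model, AUGC.

The single-compartment (standard) Tofts model describes the tissue gadolinium
concentration as the plasma concentration convolved with an exponential
impulse response,

    C_t(t) = Ktrans · ∫₀ᵗ C_p(τ) · exp(−kep (t − τ)) dτ,

with Ktrans (min⁻¹) the plasma→EES volume transfer constant, kep (min⁻¹) the
EES→plasma rate constant, and ve = Ktrans/kep the extravascular extracellular
volume fraction. Rate constants are carried in min⁻¹ throughout; time grids
are carried in seconds and converted to minutes at the model boundary.

The convolution is discretised with linear interpolation of C_p between
samples and exact integration of (linear × exponential) on each interval, so
a piecewise-linear plasma curve is propagated without quadrature error; for
a constant C_p the discrete solution equals the closed-form step response to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol, RelaxivityConstants, DEFAULT_HEMATOCRIT
from .relaxometry import T1MapResult

__all__ = [
    "ConcentrationSeries",
    "AIF",
    "PKVoxelResult",
    "ParameterMaps",
    "tofts_forward",
    "signal_to_concentration",
    "extract_aif",
    "fit_tofts_voxel",
    "fit_parameter_maps",
    "compute_augc",
]

#: Fit bounds in min⁻¹: Ktrans ∈ (1e-4, 5], kep ∈ (1e-4, 10].
DEFAULT_BOUNDS = ((1e-4, 5.0), (1e-4, 10.0))
#: kep values (min⁻¹) for the deterministic coarse-grid initialisation.
KEP_INIT_GRID = np.geomspace(1e-2, 10.0, 25)
#: Default goodness-of-fit threshold: voxels with R² below it are excluded
#: from ROI statistics.
DEFAULT_R2_THRESHOLD = 0.7


@dataclass
class ConcentrationSeries:
    """Gadolinium concentration against time.

    ``conc`` has time on the last axis and may be a single curve (1D) or a
    voxel array (e.g. X×Y×Z×T). ``baseline_idx`` indexes the pre-contrast
    frames used for signal calibration.
    """

    t_grid: np.ndarray          # seconds
    conc: np.ndarray            # mM
    baseline_idx: np.ndarray
    valid_mask: Optional[np.ndarray] = None  # spatial voxels with a usable curve

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.baseline_idx = np.asarray(self.baseline_idx, dtype=int)
        if self.conc.shape[-1] != self.t_grid.size:
            raise ValueError("conc last axis must match t_grid length")
        if self.baseline_idx.size == 0:
            raise ValueError("baseline_idx must be nonempty")


@dataclass
class AIF:
    """Arterial input function: plasma concentration C_p(t).

    ``cp`` is the whole-blood concentration divided by (1 − hematocrit).
    """

    t_grid: np.ndarray          # seconds
    cp: np.ndarray              # mM (plasma)
    hematocrit: float = DEFAULT_HEMATOCRIT

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.t_grid.shape != self.cp.shape:
            raise ValueError("t_grid and cp must have the same shape")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")


@dataclass
class PKVoxelResult:
    """Fitted Tofts parameters for one concentration curve."""

    ktrans: float               # min⁻¹
    kep: float                  # min⁻¹
    ve: float                   # Ktrans/kep
    r_squared: float
    augc: float                 # mM·min
    converged: bool


@dataclass
class ParameterMaps:
    """Voxelwise Tofts fit over a mask, with the R² exclusion mask applied."""

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    r_squared: np.ndarray
    augc: np.ndarray
    converged: np.ndarray       # bool: optimizer converged
    valid_mask: np.ndarray      # bool: converged and R² ≥ threshold
    r2_threshold: float = DEFAULT_R2_THRESHOLD


def _exp_conv(kep: float, t_min: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """∫₀ᵗ cp(τ) e^(−kep (t−τ)) dτ with cp piecewise linear on t_min.

    On a uniform grid the recursion is a first-order IIR filter and is
    evaluated with scipy.signal.lfilter; nonuniform grids fall back to an
    explicit recursion. ``1 − e^(−k h)`` is formed with expm1 so small
    kep·h does not lose precision.
    """
    n = t_min.size
    h = np.diff(t_min)
    if np.allclose(h, h[0], rtol=1e-9, atol=0.0):
        dt = h[0]
        em = -np.expm1(-kep * dt)          # 1 − exp(−kep·dt)
        e = 1.0 - em
        g1 = em / kep                      # ∫ of the constant part
        g2 = (dt - g1) / kep               # ∫ of the linear ramp part
        u = np.zeros(n)
        u[1:] = cp[:-1] * g1 + (cp[1:] - cp[:-1]) * (g2 / dt)
        return lfilter([1.0], [1.0, -e], u)
    out = np.zeros(n)
    acc = 0.0
    for i in range(1, n):
        dt = h[i - 1]
        em = -np.expm1(-kep * dt)
        g1 = em / kep
        g2 = (dt - g1) / kep
        acc = acc * (1.0 - em) + cp[i - 1] * g1 + (cp[i] - cp[i - 1]) * g2 / dt
        out[i] = acc
    return out


def tofts_forward(ktrans: float, kep: float, cp, t_grid) -> np.ndarray:
    """Tissue concentration predicted by the Tofts model.

    Parameters
    ----------
    ktrans, kep : float
        Rate constants in min⁻¹; must be positive.
    cp : array
        Plasma concentration (mM) sampled on ``t_grid``.
    t_grid : array
        Sample times in seconds, strictly increasing.
    """
    if ktrans <= 0 or kep <= 0:
        raise ValueError("ktrans and kep must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if cp.shape != t_grid.shape:
        raise ValueError("cp and t_grid must have the same length")
    if t_grid.size >= 2 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return ktrans * _exp_conv(kep, t_grid / 60.0, cp)


def _spgr_invert(signal, m0, alpha_rad, tr_ms):
    """Solve the SPGR equation for E1 given signal and M0.

    Returns (e1, in_range) where in_range flags E1 ∈ (0, 1).
    """
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * sa - signal) / (m0 * sa - signal * ca)
    in_range = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
    return e1, in_range


def signal_to_concentration(
    signal,
    t1map: T1MapResult,
    protocol: AcquisitionProtocol,
    constants: RelaxivityConstants = RelaxivityConstants(),
    baseline_idx=None,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR magnitude series to gadolinium concentration.

    The equilibrium signal M0 is calibrated per voxel from the mean of the
    pre-contrast baseline frames together with the pre-contrast T1, the SPGR
    equation is inverted frame by frame to R1(t), and

        C(t) = (R1(t) − 1/T10) / r1.

    Voxels whose T1 estimate is invalid, or where any frame's signal falls
    outside the invertible SPGR range (implied E1 ∉ (0, 1), e.g. signal at or
    above the SPGR ceiling M0·sin α), are excluded via ``valid_mask``.
    """
    signal = np.asarray(signal, dtype=float)
    t_grid = protocol.t_grid()
    if signal.shape[-1] != t_grid.size:
        raise ValueError("signal last axis must have protocol.n_dynamics frames")
    if baseline_idx is None:
        baseline_idx = protocol.baseline_indices()
    baseline_idx = np.asarray(baseline_idx, dtype=int)

    alpha = np.deg2rad(protocol.flip_dynamic)
    t1 = np.asarray(t1map.t1, dtype=float)
    r10 = 1.0 / t1                                   # ms⁻¹
    e10 = np.exp(-protocol.tr * r10)

    s0 = signal[..., baseline_idx].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 * (1.0 - e10 * np.cos(alpha)) / (np.sin(alpha) * (1.0 - e10))

    e1, in_range = _spgr_invert(signal, m0[..., None], alpha, protocol.tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = -np.log(np.where(in_range, e1, np.nan)) / protocol.tr   # ms⁻¹
        conc = (r1 - r10[..., None]) * 1000.0 / constants.r1         # mM

    valid = (
        np.asarray(t1map.valid_mask, dtype=bool)
        & (s0 > 0)
        & np.isfinite(m0)
        & (m0 > 0)
        & in_range.all(axis=-1)
    )
    conc = np.where(valid[..., None], conc, np.nan)
    return ConcentrationSeries(
        t_grid=t_grid, conc=conc, baseline_idx=baseline_idx, valid_mask=valid
    )


def extract_aif(
    series,
    artery_mask,
    t1_blood,
    protocol: AcquisitionProtocol,
    constants: RelaxivityConstants = RelaxivityConstants(),
    hematocrit: float = DEFAULT_HEMATOCRIT,
) -> AIF:
    """Extract the plasma AIF from artery voxels of a dynamic series.

    Each artery voxel's signal is converted to whole-blood concentration
    using the blood T1, the curves are averaged, and the mean is divided by
    (1 − hematocrit) to give plasma concentration.

    ``t1_blood`` may be a scalar (ms) applied to every artery voxel or an
    array/:class:`~dcepk.relaxometry.T1MapResult` aligned to the series grid.
    """
    series = np.asarray(series, dtype=float)
    artery_mask = np.asarray(artery_mask, dtype=bool)
    if artery_mask.shape != series.shape[:-1]:
        raise ValueError("artery_mask must match the spatial shape of the series")
    if not artery_mask.any():
        raise ValueError("artery_mask selects no voxels")
    if not 0 <= hematocrit < 1:
        raise ValueError("hematocrit must be in [0, 1)")

    sig = series[artery_mask]                        # (n_vox, T)
    if isinstance(t1_blood, T1MapResult):
        t1_vox = np.asarray(t1_blood.t1, dtype=float)[artery_mask]
        valid0 = np.asarray(t1_blood.valid_mask, dtype=bool)[artery_mask]
    else:
        t1_arr = np.asarray(t1_blood, dtype=float)
        t1_vox = (
            np.full(sig.shape[0], float(t1_arr))
            if t1_arr.ndim == 0
            else t1_arr[artery_mask]
        )
        valid0 = np.isfinite(t1_vox) & (t1_vox > 0)
    t1map = T1MapResult(t1=t1_vox, m0=np.ones_like(t1_vox), valid_mask=valid0)
    cs = signal_to_concentration(sig, t1map, protocol, constants)
    if not cs.valid_mask.any():
        raise ValueError("no artery voxel yielded an invertible concentration curve")
    cb = cs.conc[cs.valid_mask].mean(axis=0)         # whole-blood mean
    return AIF(t_grid=cs.t_grid, cp=cb / (1.0 - hematocrit), hematocrit=hematocrit)


def _kep_grid_bases(kep_grid: np.ndarray, t_min: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Unit-Ktrans model curves for each kep in the initialisation grid."""
    return np.stack([_exp_conv(k, t_min, cp) for k in kep_grid])


def _grid_init(ct: np.ndarray, bases: np.ndarray, kep_grid: np.ndarray, bounds):
    """Best (ktrans, kep) on the coarse grid, profiling ktrans analytically."""
    bb = np.einsum("kt,kt->k", bases, bases)
    cb = bases @ ct
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(bb > 0, cb / bb, 0.0)
    kt = np.clip(kt, bounds[0][0], bounds[0][1])
    sse = np.einsum("kt,kt->k", ct[None, :] - kt[:, None] * bases,
                    ct[None, :] - kt[:, None] * bases)
    i = int(np.argmin(sse))
    return float(kt[i]), float(np.clip(kep_grid[i], bounds[1][0], bounds[1][1]))


def fit_tofts_voxel(
    ct: ConcentrationSeries,
    aif: AIF,
    init: Optional[tuple[float, float]] = None,
    bounds=DEFAULT_BOUNDS,
    _bases: Optional[np.ndarray] = None,
) -> PKVoxelResult:
    """Nonlinear least-squares Tofts fit of one concentration curve.

    Fits (Ktrans, kep) by trust-region least squares against
    :func:`tofts_forward`; ve is derived as Ktrans/kep. When ``init`` is not
    given, a deterministic coarse grid over kep (with Ktrans profiled
    linearly at each node) supplies the starting point, making the fit
    reproducible without random multistarts. R² = 1 − SS_res/SS_tot is
    reported; a flat (zero-variance) curve yields a non-converged result
    with undefined R².
    """
    t_s = ct.t_grid
    y = np.asarray(ct.conc, dtype=float)
    if y.ndim != 1:
        raise ValueError("fit_tofts_voxel expects a single 1D curve")
    if t_s.size < 10:
        raise ValueError("need at least 10 time points to fit the Tofts model")
    if not np.array_equal(t_s, aif.t_grid):
        raise ValueError("concentration and AIF must share the same time grid")
    if not np.all(np.isfinite(y)):
        return PKVoxelResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    augc = compute_augc(ct)
    if ss_tot == 0.0:
        return PKVoxelResult(np.nan, np.nan, np.nan, np.nan, augc, False)

    t_min = t_s / 60.0
    cp = aif.cp
    if init is None:
        bases = _bases if _bases is not None else _kep_grid_bases(KEP_INIT_GRID, t_min, cp)
        x0 = _grid_init(y, bases, KEP_INIT_GRID, bounds)
    else:
        x0 = (float(init[0]), float(init[1]))
    lo = (bounds[0][0], bounds[1][0])
    hi = (bounds[0][1], bounds[1][1])
    x0 = tuple(np.clip(x0, lo, hi))

    def resid(x):
        return x[0] * _exp_conv(x[1], t_min, cp) - y

    sol = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf", xtol=1e-10)
    kt, kep = float(sol.x[0]), float(sol.x[1])
    ss_res = float(np.sum(sol.fun**2))
    r2 = 1.0 - ss_res / ss_tot
    return PKVoxelResult(
        ktrans=kt,
        kep=kep,
        ve=kt / kep,
        r_squared=r2,
        augc=augc,
        converged=bool(sol.success),
    )


def fit_parameter_maps(
    conc: ConcentrationSeries,
    aif: AIF,
    mask,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    bounds=DEFAULT_BOUNDS,
) -> ParameterMaps:
    """Voxelwise Tofts fit over a mask, with R²-based quality filtering.

    Voxels that fail to converge or fall below ``r2_threshold`` remain in
    the maps but are excluded from ``valid_mask`` (and hence from downstream
    ROI statistics).
    """
    mask = np.asarray(mask, dtype=bool)
    vol_shape = conc.conc.shape[:-1]
    if mask.shape != vol_shape:
        raise ValueError("mask must match the spatial shape of the concentration array")
    if not 0 <= r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in [0, 1]")

    shape = mask.shape
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(
        ktrans=nan.copy(), kep=nan.copy(), ve=nan.copy(),
        r_squared=nan.copy(), augc=nan.copy(),
        converged=np.zeros(shape, dtype=bool),
        valid_mask=np.zeros(shape, dtype=bool),
        r2_threshold=r2_threshold,
    )
    curve_ok = conc.valid_mask if conc.valid_mask is not None else np.ones(shape, bool)
    bases = _kep_grid_bases(KEP_INIT_GRID, conc.t_grid / 60.0, aif.cp)
    for idx in zip(*np.nonzero(mask & curve_ok)):
        cs = ConcentrationSeries(conc.t_grid, conc.conc[idx], conc.baseline_idx)
        res = fit_tofts_voxel(cs, aif, bounds=bounds, _bases=bases)
        maps.ktrans[idx] = res.ktrans
        maps.kep[idx] = res.kep
        maps.ve[idx] = res.ve
        maps.r_squared[idx] = res.r_squared
        maps.augc[idx] = res.augc
        maps.converged[idx] = res.converged
        maps.valid_mask[idx] = (
            res.converged
            and np.isfinite(res.r_squared)
            and res.r_squared >= r2_threshold
        )
    return maps


def compute_augc(ct: ConcentrationSeries) -> np.ndarray | float:
    """Area under the gadolinium concentration–time curve, in mM·min.

    Trapezoidal integral over the whole acquisition; operates on the last
    (time) axis, so a voxel array yields an AUGC map.
    """
    if ct.t_grid.size < 2:
        raise ValueError("need at least 2 time points to integrate")
    out = np.trapezoid(ct.conc, ct.t_grid / 60.0, axis=-1)
    return float(out) if np.ndim(out) == 0 else out
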