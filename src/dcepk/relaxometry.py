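"""Variable-flip-angle (dual-angle) T1 mapping for spoiled gradient echo.

The SPGR steady-state signal is

    S = M0 · sin(α) · (1 − E1) / (1 − E1 · cos(α)),   E1 = exp(−TR/T1).

With exactly two flip angles the linearisation y = S/sin(α) against
x = S/tan(α) turns the signal equation into a straight line with slope E1 and
intercept M0·(1 − E1), so T1 and M0 follow in closed form from the two
measured points — no iterative fitting is needed or used.

Perfect spoiling and a uniform transmit (B1) field are assumed; no smoothing
or regularisation is applied to the resulting maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = ["T1MapResult", "spgr_signal", "fit_t1_dual_flip"]

#: Physiological plausibility bounds for fitted T1 (ms); voxels outside are
#: flagged invalid rather than clipped.
T1_BOUNDS_MS = (50.0, 5000.0)


@dataclass
class T1MapResult:
    """Voxelwise pre-contrast T1 estimate.

    Attributes
    ----------
    t1 : ndarray
        T1 in ms; NaN where estimation failed.
    m0 : ndarray
        Equilibrium signal scale; NaN where estimation failed.
    valid_mask : ndarray of bool
        True where the closed-form solution gave E1 ∈ (0, 1) and T1 within
        the plausibility bounds.
    """

    t1: np.ndarray
    m0: np.ndarray
    valid_mask: np.ndarray


def spgr_signal(m0, t1, alpha, tr):
    """Spoiled gradient echo steady-state signal.

    Parameters
    ----------
    m0 : scalar or ndarray
        Equilibrium signal scale (arbitrary units).
    t1 : scalar or ndarray
        Longitudinal relaxation time (ms); must be positive.
    alpha : float
        Flip angle in degrees, 0 < alpha <= 90.
    tr : float
        Repetition time (ms); must be positive.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if not 0 < alpha <= 90:
        raise ValueError("alpha must be in (0, 90] degrees")
    if tr <= 0:
        raise ValueError("tr must be positive")
    a = np.deg2rad(alpha)
    e1 = np.exp(-tr / t1)
    return np.asarray(m0, dtype=float) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def fit_t1_dual_flip(
    s_low,
    s_high,
    protocol: AcquisitionProtocol,
    t1_bounds: tuple[float, float] = T1_BOUNDS_MS,
) -> T1MapResult:
    """Closed-form dual-flip-angle T1/M0 estimate.

    Parameters
    ----------
    s_low, s_high : ndarray
        SPGR magnitude signals at ``protocol.flip_t1map`` (low angle) and
        ``protocol.flip_dynamic`` (high angle), any common shape.
    protocol : AcquisitionProtocol
        Provides TR and the two flip angles.
    t1_bounds : (float, float)
        Plausibility bounds in ms; out-of-range voxels are flagged invalid.

    Notes
    -----
    Voxels where the implied E1 lies outside (0, 1) — e.g. nonpositive
    signals or a slope ≥ 1 — are marked invalid in ``valid_mask`` with NaN
    estimates; no exception is raised for them.
    """
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    if s_low.shape != s_high.shape:
        raise ValueError("s_low and s_high must have the same shape")

    a_low = np.deg2rad(protocol.flip_t1map)
    a_high = np.deg2rad(protocol.flip_dynamic)

    with np.errstate(divide="ignore", invalid="ignore"):
        x_low = s_low / np.tan(a_low)
        y_low = s_low / np.sin(a_low)
        x_high = s_high / np.tan(a_high)
        y_high = s_high / np.sin(a_high)
        e1 = (y_low - y_high) / (x_low - x_high)
        t1 = -protocol.tr / np.log(e1)
        # intercept of the linearised line is M0·(1 − E1)
        m0 = (y_low - e1 * x_low) / (1.0 - e1)

    valid = (
        (s_low > 0)
        & (s_high > 0)
        & np.isfinite(e1)
        & (e1 > 0.0)
        & (e1 < 1.0)
        & np.isfinite(t1)
        & (t1 >= t1_bounds[0])
        & (t1 <= t1_bounds[1])
        & np.isfinite(m0)
        & (m0 > 0)
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return T1MapResult(t1=t1, m0=m0, valid_mask=valid)
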