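"""Acquisition protocol and physical constants.

The default :class:`AcquisitionProtocol` reproduces a 3 T head-and-neck DCE
protocol: 3D spoiled gradient echo, TR 4.0 ms, dynamic flip angle 15° with a
2° pre-contrast acquisition for T1 mapping, 185 dynamics at 2.59 s/dynamic,
contrast injection commencing 6 s after the start of the dynamic series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionProtocol", "RelaxivityConstants", "DEFAULT_HEMATOCRIT"]

#: Assumed large-vessel hematocrit used to convert whole-blood to plasma
#: concentration.
DEFAULT_HEMATOCRIT = 0.42


@dataclass(frozen=True)
class RelaxivityConstants:
    """Contrast-agent relaxivity.

    Parameters
    ----------
    r1 : float
        Longitudinal relaxivity in s^-1 mM^-1. Default 4.5 (gadoterate
        meglumine at 3 T).
    """

    r1: float = 4.5

    def __post_init__(self) -> None:
        if not self.r1 > 0:
            raise ValueError(f"r1 relaxivity must be positive, got {self.r1}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scanner and injection timing constants for a dynamic SPGR series.

    Times are in the units conventional for each quantity: TR/TE in
    milliseconds, temporal resolution and injection timing in seconds,
    flip angles in degrees, geometry in millimetres.
    """

    tr: float = 4.0                 # repetition time (ms)
    te: float = 1.0                 # echo time (ms)
    flip_dynamic: float = 15.0      # dynamic-series flip angle (deg)
    flip_t1map: float = 2.0         # low flip angle for T1 mapping (deg)
    dt: float = 2.59                # temporal resolution (s/dynamic)
    n_dynamics: int = 185
    injection_start: float = 6.0    # contrast injection after series start (s)
    slice_thickness: float = 4.0    # mm
    matrix: tuple[int, int] = (128, 128)
    voxel_size: tuple[float, float, float] = (1.72, 1.72, 4.0)  # mm

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not (0 < self.flip_t1map < self.flip_dynamic <= 90):
            raise ValueError(
                "flip angles must satisfy 0 < flip_t1map < flip_dynamic <= 90"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_dynamics < 2:
            raise ValueError("n_dynamics must be >= 2")
        if self.injection_start < 0:
            raise ValueError("injection_start must be nonnegative")

    @property
    def duration(self) -> float:
        """Total scan duration in seconds (dt × n_dynamics)."""
        return self.dt * self.n_dynamics

    def t_grid(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_dynamics) * self.dt

    def baseline_indices(self) -> np.ndarray:
        """Indices of pre-contrast (baseline) frames.

        Frames acquired strictly before the injection command:
        floor(injection_start / dt) frames at the default protocol (2).
        """
        n_base = int(math.floor(self.injection_start / self.dt))
        if n_base < 1:
            raise ValueError(
                "protocol leaves no pre-contrast baseline frame "
                f"(injection_start={self.injection_start}, dt={self.dt})"
            )
        return np.arange(n_base)
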