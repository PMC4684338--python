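"""Per-site ROI summaries: mean parameters, volume and percentage change.

A "site" is one contoured tumor volume (primary or nodal). Voxel maps are
reduced to a single mean per parameter over the voxels that passed the
goodness-of-fit filter; sites with too few usable voxels are flagged
unanalyzable rather than summarised (mirroring the exclusion of residual
masses too small or necrotic for analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SiteRecord",
    "UnanalyzableROIError",
    "roi_mean",
    "roi_volume",
    "percent_change",
    "MIN_VALID_VOXELS",
]

#: Minimum number of filter-passing voxels for a site to be analyzable.
MIN_VALID_VOXELS = 5


class UnanalyzableROIError(ValueError):
    """The ROI has too few usable voxels to summarise."""


def roi_mean(param_map, mask, valid_mask=None,
             min_voxels: int = MIN_VALID_VOXELS) -> float:
    """Arithmetic mean of a parameter map over the usable ROI voxels.

    Only voxels inside ``mask`` that also pass ``valid_mask`` (the R² /
    convergence filter) contribute. Fewer than ``min_voxels`` usable voxels
    raises :class:`UnanalyzableROIError`.
    """
    param_map = np.asarray(param_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    sel = mask if valid_mask is None else (mask & np.asarray(valid_mask, dtype=bool))
    n = int(sel.sum())
    if n < min_voxels:
        raise UnanalyzableROIError(
            f"ROI has {n} usable voxels (< {min_voxels}); site unanalyzable"
        )
    return float(param_map[sel].mean())


def roi_volume(mask, voxel_size) -> float:
    """ROI volume in cm³ from voxel count and voxel size (mm triple)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty; volume undefined")
    vx = np.asarray(voxel_size, dtype=float)
    if vx.shape != (3,) or np.any(vx <= 0):
        raise ValueError("voxel_size must be three positive lengths in mm")
    return n * float(np.prod(vx)) / 1000.0


def percent_change(pre: float, post: float) -> float:
    """Percentage change from pre- to post-treatment: 100·(post − pre)/pre."""
    if pre == 0:
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


@dataclass
class SiteRecord:
    """One SCC site with pre-treatment (and optionally post-treatment)
    parameter means, volume, percentage changes and outcome label."""

    site_id: str
    site_type: str              # "primary" | "nodal"
    outcome: Optional[str] = None   # "SC" | "SF"
    pre: dict = field(default_factory=dict)    # parameter -> mean (+ "volume")
    post: Optional[dict] = None
    pct_change: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.site_type not in ("primary", "nodal"):
            raise ValueError("site_type must be 'primary' or 'nodal'")
        if self.outcome not in (None, "SC", "SF"):
            raise ValueError("outcome must be 'SC', 'SF' or None")
        if self.post is not None and self.pct_change is None:
            self.pct_change = {
                k: percent_change(self.pre[k], self.post[k])
                for k in self.post
                if k in self.pre and self.pre[k] != 0
            }
        if (self.pct_change is not None) != (self.post is not None):
            raise ValueError("pct_change requires both pre and post summaries")
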