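"""Pipeline composition and file I/O.

Ties the stages together — T1 mapping, concentration conversion, AIF
extraction, voxelwise Tofts fitting, ROI summaries and cohort statistics —
reading and writing standard formats (NIfTI-1 volumes, YAML configuration,
CSV tables, a JSON run manifest) so each stage is independently runnable and
every output is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocol import AcquisitionProtocol, RelaxivityConstants, DEFAULT_HEMATOCRIT
from .relaxometry import fit_t1_dual_flip, T1MapResult
from .kinetics import (
    AIF,
    DEFAULT_R2_THRESHOLD,
    ParameterMaps,
    extract_aif,
    fit_parameter_maps,
    signal_to_concentration,
)
from .roi import UnanalyzableROIError, roi_mean, roi_volume
from .stats import (
    confusion_counts,
    diagnostic_performance,
    fisher_exact_2x2,
    roc_analysis,
    univariate_logistic,
)
from .synthetic import Phantom, default_phantom_spec, generate_phantom

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "write_phantom",
    "save_map",
    "load_volume",
    "analyze_cohort",
]

MAP_NAMES = ("ktrans", "kep", "ve", "r_squared", "augc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to rerun the pipeline deterministically."""

    series_path: str
    flip_low_path: str
    artery_mask_path: str
    site_masks: dict                    # site_id -> mask path
    out_dir: str
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    constants: RelaxivityConstants = field(default_factory=RelaxivityConstants)
    hematocrit: float = DEFAULT_HEMATOCRIT
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._as_dict(), sort_keys=True))

    def _as_dict(self) -> dict:
        d = asdict(self)
        d["protocol"]["matrix"] = list(self.protocol.matrix)
        d["protocol"]["voxel_size"] = list(self.protocol.voxel_size)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        proto = d.pop("protocol", {})
        if "matrix" in proto:
            proto["matrix"] = tuple(proto["matrix"])
        if "voxel_size" in proto:
            proto["voxel_size"] = tuple(proto["voxel_size"])
        consts = d.pop("constants", {})
        return cls(
            protocol=AcquisitionProtocol(**proto),
            constants=RelaxivityConstants(**consts),
            **d,
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self._as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def save_map(data, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 with an identity affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), np.eye(4))
    nib.save(img, str(path))


def load_volume(path, stage: str = "io") -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage {stage}: missing input file {p}")
    return np.asarray(nib.load(str(p)).dataobj, dtype=np.float64)


def write_phantom(out_dir, spec=None, protocol: Optional[AcquisitionProtocol] = None,
                  noise_sigma: float = 0.0, seed: int = 0) -> PipelineConfig:
    """Generate a phantom, write it as NIfTI + sidecar YAML, return a config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = protocol or AcquisitionProtocol()
    spec = spec or default_phantom_spec(noise_sigma=noise_sigma, seed=seed)
    ph = generate_phantom(spec, protocol)

    save_map(ph.signal, out / "dynamic.nii.gz")
    save_map(ph.flip_low, out / "flip_low.nii.gz")
    save_map(ph.artery_mask.astype(np.uint8), out / "artery_mask.nii.gz",
             dtype=np.uint8)
    site_masks = {}
    for name, mask in ph.masks.items():
        p = out / f"mask_{name}.nii.gz"
        save_map(mask.astype(np.uint8), p, dtype=np.uint8)
        site_masks[name] = str(p)
    for key, vol in ph.truth.items():
        save_map(vol, out / f"truth_{key}.nii.gz")
    sidecar = {
        "protocol": {"tr": protocol.tr, "dt": protocol.dt,
                     "n_dynamics": protocol.n_dynamics,
                     "flip_dynamic": protocol.flip_dynamic,
                     "flip_t1map": protocol.flip_t1map,
                     "injection_start": protocol.injection_start},
        "hematocrit": ph.hematocrit,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "regions": {r.name: {"ktrans": r.ktrans, "kep": r.kep,
                             "t1": r.t1, "m0": r.m0}
                    for r in spec.tissue_regions},
    }
    (out / "phantom.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))

    return PipelineConfig(
        series_path=str(out / "dynamic.nii.gz"),
        flip_low_path=str(out / "flip_low.nii.gz"),
        artery_mask_path=str(out / "artery_mask.nii.gz"),
        site_masks=site_masks,
        out_dir=str(out / "results"),
        protocol=protocol,
        seed=seed,
    )


def analyze_cohort(df: pd.DataFrame, params=None, y_col: str = "outcome",
                   positive: str = "SF", roc_param: str = "pct_change_augc"):
    """Univariate logistic screen plus ROC/threshold analysis of one cohort.

    Returns (univariate table, ROCResult, DiagnosticTable, fisher p). The
    ROC treats higher values of ``roc_param`` as indicating the positive
    (treatment-failure) class; the diagnostic table is evaluated at the
    Youden-optimal threshold.
    """
    y = (df[y_col] == positive).astype(int).to_numpy()
    if params is None:
        params = [c for c in df.columns
                  if c not in ("site_id", "site_type", y_col)
                  and np.issubdtype(df[c].dtype, np.number)]
    rows = []
    for p in params:
        r = univariate_logistic(df[p].to_numpy(), y, term=p)
        rows.append({"parameter": p, "coefficient": r.coefficient,
                     "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p_value": r.p_value, "n": r.n})
    uni = pd.DataFrame(rows)

    roc = roc_analysis(df[roc_param].to_numpy(), y, positive_direction="higher")
    tp, fp, tn, fn = confusion_counts(df[roc_param].to_numpy(), y,
                                      roc.optimal_threshold)
    table = diagnostic_performance(tp, fp, tn, fn,
                                   threshold=roc.optimal_threshold)
    p_fisher = fisher_exact_2x2([[tp, fp], [fn, tn]])
    return uni, roc, table, p_fisher


def _lib_versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    return {
        "dcepk": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run T1 map → concentration → AIF → fit → ROI summaries.

    Writes parameter maps (float32 NIfTI), the AIF (CSV), a per-site summary
    table (CSV) and a JSON manifest with library versions, the seed and a
    hash of the configuration. Returns the site summary table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol

    series = load_volume(config.series_path, stage="load-series")
    flip_low = load_volume(config.flip_low_path, stage="load-flip-low")
    artery_mask = load_volume(config.artery_mask_path,
                              stage="load-artery-mask").astype(bool)
    if series.ndim != 4:
        raise PipelineError("stage load-series: expected a 4D dynamic series")
    if series.shape[-1] != protocol.n_dynamics:
        raise PipelineError(
            "stage load-series: series has "
            f"{series.shape[-1]} frames, protocol expects {protocol.n_dynamics}"
        )

    # stage t1map: dual-angle closed form; the high-angle point is the mean
    # pre-contrast frame of the dynamic series itself
    s_high = series[..., protocol.baseline_indices()].mean(axis=-1)
    t1map = fit_t1_dual_flip(flip_low, s_high, protocol)
    save_map(t1map.t1, out / "t1.nii.gz")
    save_map(t1map.m0, out / "m0.nii.gz")

    # stage concentration
    conc = signal_to_concentration(series, t1map, protocol, config.constants)

    # stage aif: blood T1 from the same dual-angle map at artery voxels
    if not artery_mask.any():
        raise PipelineError("stage aif: artery mask selects no voxels")
    aif = extract_aif(series, artery_mask, t1map, protocol, config.constants,
                      config.hematocrit)
    pd.DataFrame({"t_seconds": aif.t_grid, "cp_mM": aif.cp}).to_csv(
        out / "aif.csv", index=False
    )

    # stage fit + roistats
    rows = []
    excluded = {}
    for site_id, mask_path in sorted(config.site_masks.items()):
        mask = load_volume(mask_path, stage=f"load-mask-{site_id}").astype(bool)
        maps = fit_parameter_maps(conc, aif, mask, config.r2_threshold)
        for name in MAP_NAMES:
            save_map(getattr(maps, name), out / f"{name}_{site_id}.nii.gz")
        excluded[site_id] = int(mask.sum() - maps.valid_mask.sum())
        row = {"site_id": site_id,
               "n_voxels": int(mask.sum()),
               "n_valid": int(maps.valid_mask.sum()),
               "volume_cm3": roi_volume(mask, protocol.voxel_size)}
        try:
            for name in ("ktrans", "kep", "ve", "augc"):
                row[f"mean_{name}"] = roi_mean(getattr(maps, name), mask,
                                               maps.valid_mask)
            row["analyzable"] = True
        except UnanalyzableROIError:
            for name in ("ktrans", "kep", "ve", "augc"):
                row[f"mean_{name}"] = np.nan
            row["analyzable"] = False
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "site_summary.csv", index=False, float_format="%.9g")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _lib_versions(),
        "r2_threshold": config.r2_threshold,
        "excluded_voxels": excluded,
        "n_sites": len(rows),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return summary
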