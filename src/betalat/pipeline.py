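"""Config-driven orchestration of the full lateralization analysis.

``run_meg_pipeline`` chains the MEG stages — window cutting, multitaper
CSDs, common DICS filter, trialwise source power, ROI-restricted cluster
permutation statistics with the uncorrected fallback, laterality indices
and dominance categories. ``run_fmri_pipeline`` applies the volumetric
thresholding route to an fMRI-style t-map. ``roi_agreement`` cross-tabulates
two per-subject category series per ROI.

The default :class:`PipelineConfig` encodes the canonical analysis
settings: 24 Hz centre frequency with 11 Hz smoothing, 10% regularization,
0-700 ms pre-stimulus baseline vs 300-1000 ms active windows, 10,000
permutations with critical t 1.65 (fallback 1.97 uncorrected), fMRI
threshold t 3.13 with extent 10, and dominance cutoffs +-0.1 (MEG) /
+-0.2 (fMRI).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import inference, laterality, synthetic
from .agreement import AgreementReport, LabelSeries, agreement_report
from .beamformer import condition_power, dics_common_filter, percent_change_map, sphere_leadfield
from .core import HeadModel, InvalidInputError, SensorEpochs, SourceGrid, SourceStatMap
from .laterality import LateralityResult, ROIDefinition
from .spectral import combine_csd, epoch_windows, multitaper_csd

logger = logging.getLogger("betalat")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults reproduce the canonical settings."""

    center_freq: float = 24.0
    halfbandwidth: float = 11.0
    lambda_frac: float = 0.1
    baseline_window: tuple[float, float] = (-0.7, 0.0)
    active_window: tuple[float, float] = (0.3, 1.0)
    n_perm: int = 10_000
    t_crit: float = 1.65
    alpha: float = 0.05
    t_fallback: float = 1.97
    fmri_t_crit: float = 3.13
    fmri_min_extent: int = 10
    meg_cutoff: float = 0.1
    fmri_cutoff: float = 0.2
    top_fraction: float = 0.1
    grid_spacing: float = 10.0
    source_connectivity: int = 6
    fmri_connectivity: int = 18
    tfr_fmin: float = 1.0
    tfr_fmax: float = 45.0
    tfr_n_cycles: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["active_window"] = list(self.active_window)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_window", "active_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class MEGPipelineResult:
    """All artefacts of one subject's MEG analysis."""

    thresholded: SourceStatMap  # t-values of surviving voxels, 0 elsewhere
    raw_t: SourceStatMap
    percent_change: SourceStatMap
    cluster: inference.ClusterTestResult
    laterality: list[LateralityResult]
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def laterality_frame(self) -> pd.DataFrame:
        return laterality_frame(self.laterality)


def laterality_frame(results: list[LateralityResult], subject: Any = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row.pop("info")
        if subject is not None:
            row["subject"] = subject
        rows.append(row)
    return pd.DataFrame(rows)


def _stat_voxels(grid: SourceGrid, rois: list[ROIDefinition]) -> np.ndarray:
    """Global indices of inside voxels inside any analysis ROI."""
    wanted: set[int] = set()
    for roi in rois:
        wanted |= roi.left_labels | roi.right_labels
    sel = np.isin(grid.atlas_labels, list(wanted)) & grid.inside_mask
    return np.flatnonzero(sel)


def run_meg_pipeline(
    epochs: SensorEpochs,
    head: HeadModel,
    grid: SourceGrid,
    rois: list[ROIDefinition],
    cfg: PipelineConfig | None = None,
) -> MEGPipelineResult:
    """Beta-desynchronization lateralization for one subject.

    Statistics are restricted to the voxels of the analysis ROIs; the
    cluster-corrected map falls back to the uncorrected t > ``t_fallback``
    rule when no cluster survives.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    base_seg, act_seg = epoch_windows(epochs, cfg.baseline_window, cfg.active_window)
    csd_base = multitaper_csd(base_seg, epochs.sfreq, cfg.center_freq,
                              cfg.halfbandwidth, condition="baseline")
    csd_act = multitaper_csd(act_seg, epochs.sfreq, cfg.center_freq,
                             cfg.halfbandwidth, condition="active")
    csd_comb = combine_csd(csd_base, csd_act)
    lf = sphere_leadfield(head, grid)
    filt = dics_common_filter(csd_comb, lf, cfg.lambda_frac)
    power = condition_power(filt, csd_base, csd_act)
    pchange = percent_change_map(power)

    inside = grid.inside_indices
    stat_vox = _stat_voxels(grid, rois)
    col = np.searchsorted(inside, stat_vox)  # columns of the power arrays
    adj = inference.grid_adjacency(grid, stat_vox, cfg.source_connectivity)
    cluster = inference.cluster_permutation_test(
        power.active_trials[:, col], power.baseline_trials[:, col], adj,
        n_perm=cfg.n_perm, t_crit=cfg.t_crit, alpha=cfg.alpha, seed=cfg.seed)

    n_grid = grid.n_grid
    mask = np.zeros(n_grid, bool)
    mask[stat_vox] = True
    raw_vals = np.zeros(n_grid)
    raw_vals[stat_vox] = cluster.tvals
    raw_t = SourceStatMap(values=raw_vals, mask=mask, grid=grid,
                          info={"kind": "paired_t", "df": epochs.n_trials - 1})
    if cluster.surviving.any():
        thr_vals = np.zeros(n_grid)
        thr_vals[stat_vox] = cluster.thresholded
        thresholded = SourceStatMap(
            values=thr_vals, mask=mask, grid=grid,
            info={"critical_t": cfg.t_crit, "corrected": True,
                  "rule": "cluster-corrected", "alpha": cfg.alpha})
    else:
        logger.warning("no cluster survived; applying uncorrected fallback t > %.2f",
                       cfg.t_fallback)
        thresholded = inference.fallback_threshold(raw_t, cfg.t_fallback)
    results = laterality.lateralize(thresholded, rois, cfg.meg_cutoff, modality="MEG")
    logger.info("MEG pipeline: %d trials, %d stat voxels, status=%s, %.2f s",
                epochs.n_trials, stat_vox.size, cluster.status,
                time.perf_counter() - t0)
    return MEGPipelineResult(thresholded=thresholded, raw_t=raw_t,
                             percent_change=pchange, cluster=cluster,
                             laterality=results, config=cfg.to_dict())


@dataclass
class FMRIPipelineResult:
    thresholded: SourceStatMap
    laterality: list[LateralityResult]
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def laterality_frame(self) -> pd.DataFrame:
        return laterality_frame(self.laterality)


def run_fmri_pipeline(
    tmap: SourceStatMap,
    rois: list[ROIDefinition],
    cfg: PipelineConfig | None = None,
    method: str = "extent",
) -> FMRIPipelineResult:
    """Threshold an fMRI t-map and lateralize at the fMRI cutoff.

    ``method`` selects the thresholding route: ``"extent"`` (t > 3.13 with
    10-voxel extent) or ``"top_percent"`` (individualized upper fraction of
    positive voxels).
    """
    cfg = cfg or PipelineConfig()
    if method == "extent":
        thr = laterality.fmri_threshold_map(tmap, cfg.fmri_t_crit,
                                            cfg.fmri_min_extent,
                                            cfg.fmri_connectivity)
    elif method == "top_percent":
        thr = laterality.top_percent_threshold(tmap, cfg.top_fraction)
    else:
        raise InvalidInputError("method must be 'extent' or 'top_percent'")
    results = laterality.lateralize(thr, rois, cfg.fmri_cutoff, modality="fMRI")
    return FMRIPipelineResult(thresholded=thr, laterality=results,
                              config=cfg.to_dict())


def roi_agreement(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alphabet: tuple[str, ...],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, AgreementReport]:
    """Per-ROI agreement between two long category frames.

    Both frames need columns ``subject``, ``roi``, ``category`` and may
    carry a ``modality`` column used for labelling. Subjects are aligned by
    sorted id; a mismatch raises.
    """
    reports: dict[str, AgreementReport] = {}
    for roi in sorted(set(a["roi"]) | set(b["roi"])):
        sa = a[a["roi"] == roi].sort_values("subject")
        sb = b[b["roi"] == roi].sort_values("subject")
        if list(sa["subject"]) != list(sb["subject"]):
            raise InvalidInputError(f"ROI {roi}: subject sets differ between series")
        la = LabelSeries(tuple(sa["subject"]), tuple(sa["category"]), alphabet,
                         modality=str(sa["modality"].iloc[0]) if "modality" in sa else "a")
        lb = LabelSeries(tuple(sb["subject"]), tuple(sb["category"]), alphabet,
                         modality=str(sb["modality"].iloc[0]) if "modality" in sb else "b")
        reports[roi] = agreement_report(la, lb, n_perm=n_perm, seed=seed)
    return reports


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the deterministic fixture bundle used by examples and tests.

    Produces (i) the reference-cohort aggregate table as CSV, (ii) a small
    synthetic MEG subject with left-lateralized beta desynchronization
    (HDF5 container with geometry), (iii) a synthetic left-dominant t-map
    (NIfTI) and (iv) the resolved default configuration (YAML).
    """
    from . import cohort, io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["cohort"] = out / "reference_cohort.csv"
    cohort.cohort_table().to_csv(paths["cohort"], index=False)

    head, grid = synthetic.make_toy_anatomy(n_chan=32, grid_spacing=20.0, seed=seed)
    left_label = synthetic.TOY_ROI_LABELS["IFG"][0][0]
    src_vox = _closest_voxel_in_label(grid, left_label)
    cfg = synthetic.SimulationConfig(
        n_trials=48, sfreq=480.0,
        sources=(synthetic.SourceSpec(grid_index=src_vox),), seed=seed)
    epochs = synthetic.simulate_epochs(cfg, head, grid)
    paths["epochs"] = out / "synthetic_subject.h5"
    io.save_epochs(paths["epochs"], epochs, grid)

    tmap = synthetic.simulate_tmap(grid, [(left_label, 8.0, 25.0)],
                                   noise_sd=0.5, seed=seed)
    paths["tmap"] = out / "synthetic_tmap.nii"
    io.save_map_nifti(tmap, paths["tmap"])

    paths["config"] = out / "config.yaml"
    PipelineConfig().to_yaml(paths["config"])
    return paths


def _closest_voxel_in_label(grid: SourceGrid, label: int) -> int:
    """The label voxel nearest its region centroid (a stable source site)."""
    idx = grid.label_indices(label)
    center = grid.positions[idx].mean(axis=0)
    return int(idx[np.argmin(np.linalg.norm(grid.positions[idx] - center, axis=1))])
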