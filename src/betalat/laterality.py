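"""Laterality indices and dominance classification from thresholded maps.

The laterality index over a pair of homologous regions of interest is

    LI = (S_left - S_right) / (S_left + S_right),

where S is either the sum of threshold-surviving t-values or the count of
threshold-surviving voxels on each side. LI is +1 when only the left side
survives, -1 when only the right side does, and undefined when neither
does. Dominance categories follow the conventional cutoffs: MEG uses
+-0.1, fMRI +-0.2; indices at or beyond the cutoff are lateralized
(boundary inclusive), values strictly between are bilateral. For agreement
statistics against the Wada test, the trichotomous categories are
dichotomized to Left vs Atypical (right or bilateral).

fMRI t-maps are thresholded the standard single-subject way: t > 3.13
(p < 0.001 uncorrected) with a minimum cluster extent of 10 voxels
(18-connectivity), or alternatively by keeping the top fraction of
positive-t voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .core import InvalidInputError, InvalidParameterError, SourceStatMap

LEFT = "left"
RIGHT = "right"
BILATERAL = "bilateral"
UNDETERMINED = "undetermined"
DICH_LEFT = "Left"
DICH_ATYPICAL = "Atypical"

MEG_CUTOFF = 0.1
FMRI_CUTOFF = 0.2
FMRI_T_CRIT = 3.13
FMRI_MIN_EXTENT = 10


@dataclass(frozen=True)
class ROIDefinition:
    """A named pair of homologous left/right atlas label sets."""

    name: str
    left_labels: frozenset[int]
    right_labels: frozenset[int]

    def __post_init__(self) -> None:
        left = frozenset(int(x) for x in self.left_labels)
        right = frozenset(int(x) for x in self.right_labels)
        if not left or not right:
            raise InvalidParameterError("ROI label sets must be non-empty")
        if left & right:
            raise InvalidParameterError("left and right label sets must be disjoint")
        object.__setattr__(self, "left_labels", left)
        object.__setattr__(self, "right_labels", right)


def default_rois(mapping: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]) -> list[ROIDefinition]:
    """Build ROI definitions from a ``{name: (left_labels, right_labels)}``
    table (editable configuration; the synthetic module ships a toy one)."""
    return [ROIDefinition(name, frozenset(l), frozenset(r))
            for name, (l, r) in mapping.items()]


@dataclass
class LateralityResult:
    """Per-ROI aggregates, LI values and dominance categories."""

    roi: str
    sum_t_left: float
    sum_t_right: float
    voxels_left: int
    voxels_right: int
    li_sum_t: float | None
    li_voxel_count: float | None
    category: str
    category_dichotomous: str
    cutoff: float
    modality: str = ""
    info: dict[str, Any] = field(default_factory=dict)


def _connected_extent_filter(volume: np.ndarray, min_extent: int,
                             connectivity: int) -> np.ndarray:
    """Zero out connected suprathreshold components smaller than
    ``min_extent`` voxels."""
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labels, n = ndimage.label(volume > 0, structure=structure)
    if n == 0:
        return np.zeros_like(volume)
    sizes = ndimage.sum_labels(np.ones_like(volume), labels, index=np.arange(1, n + 1))
    keep = np.isin(labels, 1 + np.flatnonzero(sizes >= min_extent))
    return np.where(keep, volume, 0.0)


def fmri_threshold_map(tmap: SourceStatMap, t_crit: float = FMRI_T_CRIT,
                       min_extent: int = FMRI_MIN_EXTENT,
                       connectivity: int = 18) -> SourceStatMap:
    """Uncorrected t-threshold plus cluster-extent filter on a volume map."""
    vol = np.where(tmap.mask.reshape(tmap.grid.shape),
                   tmap.to_volume(), 0.0)
    vol = np.where(vol > t_crit, vol, 0.0)
    vol = _connected_extent_filter(vol, min_extent, connectivity)
    return tmap.copy_with(vol.ravel(), critical_t=t_crit, min_extent=min_extent,
                          corrected=False, rule="uncorrected+extent")


def top_percent_threshold(tmap: SourceStatMap, fraction: float = 0.1) -> SourceStatMap:
    """Keep the highest ``ceil(fraction * n_positive)`` positive-t voxels.

    Ties at the cut value are all retained (stable rule), so the survivor
    set can slightly exceed the nominal count but is reproducible and
    nested across fractions.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidParameterError("fraction must be in (0, 1)")
    vals = np.where(tmap.mask, tmap.values, 0.0)
    pos = vals[vals > 0]
    if pos.size == 0:
        return tmap.copy_with(np.zeros_like(vals), rule="top-percent",
                              fraction=fraction, corrected=False)
    k = int(np.ceil(fraction * pos.size))
    cut = np.sort(pos)[::-1][k - 1]
    out = np.where(vals >= cut, vals, 0.0)
    return tmap.copy_with(out, rule="top-percent", fraction=fraction,
                          cut_value=float(cut), corrected=False)


def li_from_aggregates(left: float, right: float) -> float | None:
    """(L - R) / (L + R); ``None`` (undefined) when both sides are zero."""
    if left < 0 or right < 0:
        raise InvalidInputError("aggregates must be non-negative")
    total = left + right
    if total == 0:
        return None
    return (left - right) / total


def laterality_index(
    thresholded: SourceStatMap,
    roi: ROIDefinition,
    method: str = "sum_t",
) -> tuple[float | None, dict[str, float]]:
    """Laterality index of a thresholded map over one ROI pair.

    ``method`` is ``"sum_t"`` (sum of surviving t-values) or
    ``"voxel_count"``. Zeros in the map are removed voxels. Returns the LI
    (``None`` when undefined) plus the left/right aggregates.
    """
    labels = thresholded.grid.atlas_labels
    present = set(np.unique(labels))
    wanted = set(roi.left_labels) | set(roi.right_labels)
    if not wanted <= present:
        raise InvalidInputError(
            f"ROI {roi.name}: labels {sorted(wanted - present)} absent from atlas")
    vals = np.where(thresholded.mask, thresholded.values, 0.0)
    left_sel = np.isin(labels, list(roi.left_labels))
    right_sel = np.isin(labels, list(roi.right_labels))
    surv = vals > 0
    agg = {
        "sum_t_left": float(vals[left_sel & surv].sum()),
        "sum_t_right": float(vals[right_sel & surv].sum()),
        "voxels_left": int((left_sel & surv).sum()),
        "voxels_right": int((right_sel & surv).sum()),
    }
    if method == "sum_t":
        li = li_from_aggregates(agg["sum_t_left"], agg["sum_t_right"])
    elif method == "voxel_count":
        li = li_from_aggregates(agg["voxels_left"], agg["voxels_right"])
    else:
        raise InvalidParameterError("method must be 'sum_t' or 'voxel_count'")
    return li, agg


def classify_li(li: float | None, cutoff: float) -> str:
    """Trichotomous dominance: left if LI >= cutoff, right if LI <= -cutoff,
    bilateral in between, undetermined for an undefined LI."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    if li is None or (isinstance(li, float) and np.isnan(li)):
        return UNDETERMINED
    if li >= cutoff:
        return LEFT
    if li <= -cutoff:
        return RIGHT
    return BILATERAL


def dichotomize(category: str) -> str:
    """Left stays Left; right and bilateral collapse to Atypical."""
    if category == LEFT:
        return DICH_LEFT
    if category in (RIGHT, BILATERAL):
        return DICH_ATYPICAL
    if category == UNDETERMINED:
        return UNDETERMINED
    raise InvalidParameterError(f"unknown category {category!r}")


def lateralize(
    thresholded: SourceStatMap,
    rois: list[ROIDefinition],
    cutoff: float,
    modality: str = "",
) -> list[LateralityResult]:
    """Compute both LI variants and categories for every ROI."""
    out = []
    for roi in rois:
        li_t, agg = laterality_index(thresholded, roi, "sum_t")
        li_v, _ = laterality_index(thresholded, roi, "voxel_count")
        cat = classify_li(li_t, cutoff)
        out.append(LateralityResult(
            roi=roi.name, li_sum_t=li_t, li_voxel_count=li_v,
            category=cat, category_dichotomous=dichotomize(cat),
            cutoff=cutoff, modality=modality, **agg,
        ))
    return out
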