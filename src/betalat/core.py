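"""Shared data containers for the lateralization pipeline.

The coordinate conventions used throughout:

* source space: millimetres, origin at the centre of the conducting sphere,
  x < 0 is the left hemisphere, x > 0 the right;
* sensor space: metres, same origin and axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class InvalidParameterError(ValueError):
    """A parameter violates an operation's contract."""


class InvalidInputError(ValueError):
    """Input data violate an operation's contract."""


class NumericFailureError(RuntimeError):
    """A numerical step failed (e.g. a singular covariance matrix)."""


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor plus magnetometer geometry.

    Attributes
    ----------
    sphere_center : (3,) array, metres.
    sensor_positions : (n_chan, 3) array, metres.
    sensor_orientations : (n_chan, 3) array of unit vectors (coil normals).
    """

    sphere_center: np.ndarray
    sensor_positions: np.ndarray
    sensor_orientations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sphere_center", np.asarray(self.sphere_center, float))
        object.__setattr__(self, "sensor_positions", np.asarray(self.sensor_positions, float))
        object.__setattr__(self, "sensor_orientations", np.asarray(self.sensor_orientations, float))
        norms = np.linalg.norm(self.sensor_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidParameterError("sensor orientations must be unit vectors")

    @property
    def n_chan(self) -> int:
        return self.sensor_positions.shape[0]


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic source grid with an inside-brain mask and atlas labels.

    ``positions`` enumerate the full grid (outside points included) in
    row-major (ij-indexed) order so that ``positions.reshape(*shape, 3)``
    recovers the volume. ``atlas_labels`` are nonzero only inside the brain;
    label 0 means unlabeled.
    """

    positions: np.ndarray  # (n_grid, 3) mm
    inside_mask: np.ndarray  # (n_grid,) bool
    atlas_labels: np.ndarray  # (n_grid,) int
    spacing: float  # mm
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InvalidParameterError("grid spacing must be positive")
        if np.any(self.atlas_labels[~self.inside_mask] != 0):
            raise InvalidInputError("atlas labels must be zero outside the brain")

    @property
    def n_grid(self) -> int:
        return self.positions.shape[0]

    @property
    def inside_indices(self) -> np.ndarray:
        return np.flatnonzero(self.inside_mask)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine (RAS-like, for NIfTI export)."""
        aff = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        aff[:3, 3] = self.positions[0]
        return aff

    def label_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.atlas_labels == label)

    def label_centroid(self, label: int) -> np.ndarray:
        idx = self.label_indices(label)
        if idx.size == 0:
            raise InvalidParameterError(f"atlas label {label} not present in grid")
        return self.positions[idx].mean(axis=0)


@dataclass(frozen=True)
class SensorEpochs:
    """Stimulus-locked trials: ``data`` is (n_trials, n_chan, n_samples)."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to stimulus onset
    sfreq: float
    head: HeadModel | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidInputError("epoch data must be (n_trials, n_chan, n_samples)")
        if self.data.shape[2] != self.times.shape[0]:
            raise InvalidInputError("n_samples must equal len(times)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_chan(self) -> int:
        return self.data.shape[1]


@dataclass
class SourceStatMap:
    """Per-voxel statistic on a :class:`SourceGrid`.

    ``values`` has one entry per grid point (zero where removed or not
    evaluated); ``mask`` marks the evaluated elements. ``info`` records the
    thresholding provenance (critical t, corrected flag, rule name, ...).
    """

    values: np.ndarray  # (n_grid,)
    mask: np.ndarray  # (n_grid,) bool: evaluated elements
    grid: SourceGrid
    info: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != (self.grid.n_grid,) or self.mask.shape != self.values.shape:
            raise InvalidInputError("map values/mask must match the grid size")

    def to_volume(self) -> np.ndarray:
        return self.values.reshape(self.grid.shape)

    def copy_with(self, values: np.ndarray, **info: Any) -> "SourceStatMap":
        new_info = dict(self.info)
        new_info.update(info)
        return SourceStatMap(values=values, mask=self.mask.copy(), grid=self.grid, info=new_info)
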