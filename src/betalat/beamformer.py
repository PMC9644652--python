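"""Spherical-conductor leadfields and DICS spatial filtering.

The forward model is the analytic magnetic field of a current dipole inside
a homogeneous conducting sphere (Sarvas' formula). Two of its properties
carry through the whole pipeline: radially oriented dipoles are magnetically
silent, and the field outside the sphere does not depend on the conductivity
profile.

Dynamic Imaging of Coherent Sources (DICS) estimates narrowband source
power by a linearly constrained minimum-variance spatial filter built from
the sensor cross-spectral density (CSD). A single *common* filter is
computed from the pooled conditions and applied to each condition and to
every single trial, so that baseline/active power contrasts are not biased
by condition-specific filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .core import (
    HeadModel,
    InvalidInputError,
    InvalidParameterError,
    NumericFailureError,
    SourceGrid,
    SourceStatMap,
)

if TYPE_CHECKING:  # pragma: no cover
    from .spectral import CrossSpectrum

_MU0_OVER_4PI = 1e-7  # T·m/A


def dipole_field(head: HeadModel, pos_mm: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Magnetometer readings of a current dipole in a conducting sphere.

    Parameters
    ----------
    pos_mm : (3,) dipole position in grid coordinates (mm, origin at the
        sphere centre).
    moment : (3,) dipole moment in A·m.

    Returns
    -------
    (n_chan,) field projected onto each sensor's orientation, in tesla.
    """
    r0 = np.asarray(pos_mm, float) / 1000.0  # m, relative to sphere centre
    if np.linalg.norm(r0) < 1e-9:
        raise InvalidParameterError("dipole at the sphere centre has no tangential frame")
    q = np.asarray(moment, float)
    r = head.sensor_positions - head.sphere_center  # (n, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= np.linalg.norm(r0)):
        raise InvalidParameterError("all sensors must lie strictly outside the source radius")
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - r0_dot_r)
    grad_f = (
        (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0[None, :]
    )
    q_x_r0 = np.cross(q, r0)
    b = _MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0[None, :] - (r @ q_x_r0)[:, None] * grad_f
    )
    return np.einsum("ij,ij->i", b, head.sensor_orientations)


@dataclass(frozen=True)
class LeadField:
    """Forward gains: ``gain[:, 3*v:3*v+3]`` maps a dipole at inside voxel
    ``v`` (unit moments along x, y, z) to the sensors."""

    gain: np.ndarray  # (n_chan, 3 * n_inside)
    grid: SourceGrid

    @property
    def n_inside(self) -> int:
        return self.gain.shape[1] // 3

    def voxel_gain(self, v: int) -> np.ndarray:
        """(n_chan, 3) gain matrix of inside voxel ``v``."""
        return self.gain[:, 3 * v : 3 * v + 3]


def sphere_leadfield(head: HeadModel, grid: SourceGrid) -> LeadField:
    """Analytic dipole-in-sphere leadfield at every inside grid point."""
    inside = grid.inside_indices
    sensor_radius = np.linalg.norm(head.sensor_positions - head.sphere_center, axis=1).min()
    src_radius = np.linalg.norm(grid.positions[inside], axis=1).max() / 1000.0
    if src_radius >= sensor_radius:
        raise InvalidParameterError("inside grid points must lie strictly inside the sensor radius")
    gain = np.empty((head.n_chan, 3 * inside.size))
    eye = np.eye(3)
    for j, g in enumerate(inside):
        if np.linalg.norm(grid.positions[g]) < 1e-9:
            # the conductor centre is magnetically silent (zero external field)
            gain[:, 3 * j : 3 * j + 3] = 0.0
            continue
        for k in range(3):
            gain[:, 3 * j + k] = dipole_field(head, grid.positions[g], eye[k])
    return LeadField(gain=gain, grid=grid)


@dataclass(frozen=True)
class SpatialFilter:
    """Scalar (orientation-optimised) DICS filter per inside voxel."""

    weights: np.ndarray  # (n_inside, n_chan)
    orientations: np.ndarray  # (n_inside, 3) unit vectors
    lambda_frac: float
    grid: SourceGrid


def dics_common_filter(
    csd_combined: "CrossSpectrum",
    lf: LeadField,
    lambda_frac: float = 0.1,
) -> SpatialFilter:
    """Unit-gain minimum-variance filter from the pooled-condition CSD.

    The real part of the CSD is regularised as
    ``C_r = Re(C) + lambda_frac * trace(Re(C)) / n_chan * I``.
    Per voxel the source orientation is the direction maximising filter
    output power (the eigendirection minimising ``l' C_r^{-1} l`` within the
    numerically non-silent column space of the local leadfield), and the
    scalar weights are ``C_r^{-1} l / (l' C_r^{-1} l)``.
    """
    if lambda_frac < 0:
        raise InvalidParameterError("lambda_frac must be >= 0")
    c = np.real(csd_combined.csd)
    n_chan = c.shape[0]
    if lf.gain.shape[0] != n_chan:
        raise InvalidInputError("leadfield and CSD channel counts differ")
    c_r = c + lambda_frac * (np.trace(c) / n_chan) * np.eye(n_chan)
    try:
        c_inv = np.linalg.inv(c_r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - depends on data rank
        raise NumericFailureError(
            "regularised CSD is singular; increase lambda_frac"
        ) from exc
    cond = np.linalg.cond(c_r)
    if cond > 1e12:
        raise NumericFailureError(
            f"regularised CSD is ill-conditioned (cond={cond:.2e}); increase lambda_frac"
        )
    n_inside = lf.n_inside
    weights = np.empty((n_inside, n_chan))
    orients = np.empty((n_inside, 3))
    for v in range(n_inside):
        l3 = lf.voxel_gain(v)  # (n_chan, 3)
        if not np.any(l3):
            # magnetically silent voxel (e.g. the sphere centre)
            weights[v] = 0.0
            orients[v] = (0.0, 0.0, 1.0)
            continue
        # Restrict to the numerically non-silent subspace (the sphere model
        # has an exactly silent radial direction).
        u, s, vt = np.linalg.svd(l3, full_matrices=False)
        keep = s > max(1e-8 * s[0], 0.0)
        basis = vt[keep].T  # (3, r)
        lr = l3 @ basis  # (n_chan, r)
        m = lr.T @ c_inv @ lr  # (r, r), SPD
        evals, evecs = np.linalg.eigh(m)
        q = basis @ evecs[:, 0]  # minimises l' C^-1 l -> maximises power
        q = q / np.linalg.norm(q)
        # deterministic sign: largest-magnitude component positive
        if q[np.argmax(np.abs(q))] < 0:
            q = -q
        l = l3 @ q
        ci_l = c_inv @ l
        denom = float(l @ ci_l)
        if denom <= 0:
            raise NumericFailureError(f"non-positive projected power at voxel {v}")
        weights[v] = ci_l / denom
        orients[v] = q
    return SpatialFilter(weights=weights, orientations=orients,
                         lambda_frac=lambda_frac, grid=lf.grid)


@dataclass(frozen=True)
class SourcePowerMap:
    """Per-voxel DICS power for both conditions, per trial and averaged."""

    baseline_trials: np.ndarray  # (n_trials, n_inside)
    active_trials: np.ndarray  # (n_trials, n_inside)
    grid: SourceGrid

    @property
    def baseline(self) -> np.ndarray:
        return self.baseline_trials.mean(axis=0)

    @property
    def active(self) -> np.ndarray:
        return self.active_trials.mean(axis=0)


def source_power(filt: SpatialFilter, csd: "CrossSpectrum") -> np.ndarray:
    """Per-trial source power ``w Re(C_trial) w'`` for every inside voxel.

    Returns an (n_trials, n_inside) array; the condition mean equals the
    power computed from the condition-average CSD by linearity.
    """
    per_trial = np.real(csd.per_trial_csd)
    if per_trial.shape[1] != filt.weights.shape[1]:
        raise InvalidInputError("filter and CSD channel counts differ")
    return np.einsum("vc,tcd,vd->tv", filt.weights, per_trial, filt.weights)


def condition_power(filt: SpatialFilter, csd_baseline: "CrossSpectrum",
                    csd_active: "CrossSpectrum") -> SourcePowerMap:
    """Apply one common filter to both conditions (trialwise)."""
    return SourcePowerMap(
        baseline_trials=source_power(filt, csd_baseline),
        active_trials=source_power(filt, csd_active),
        grid=filt.grid,
    )


def percent_change_map(power: SourcePowerMap) -> SourceStatMap:
    """``100 * (active - baseline) / baseline`` per voxel.

    Voxels with zero baseline power are flagged invalid (excluded from the
    evaluated mask) rather than producing infinities.
    """
    base = power.baseline
    act = power.active
    grid = power.grid
    values = np.zeros(grid.n_grid)
    mask = np.zeros(grid.n_grid, bool)
    inside = grid.inside_indices
    valid = base > 0
    values[inside[valid]] = 100.0 * (act[valid] - base[valid]) / base[valid]
    mask[inside[valid]] = True
    return SourceStatMap(values=values, mask=mask, grid=grid,
                         info={"kind": "percent_change", "invalid_baseline": int((~valid).sum())})
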