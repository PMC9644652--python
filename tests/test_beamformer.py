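"""Spherical forward model and DICS filter against closed-form oracles."""

import numpy as np
import pytest

from betalat import (
    InvalidParameterError,
    LeadField,
    SourceGrid,
    condition_power,
    dics_common_filter,
    dipole_field,
    percent_change_map,
    sphere_leadfield,
)
from betalat import spectral
from betalat.beamformer import SourcePowerMap
from betalat.spectral import CrossSpectrum, epoch_windows, multitaper_csd

from conftest import erd_epochs, source_voxel


def toy_csd(c, n_trials=1):
    c = np.asarray(c, complex)
    per_trial = np.tile(c, (n_trials, 1, 1))
    return CrossSpectrum(csd=c, per_trial_csd=per_trial, center_freq=24.0,
                         halfbandwidth=11.0, n_tapers=1)


def toy_grid(n_vox):
    """Degenerate grid container for hand-built leadfields."""
    positions = np.column_stack([np.arange(n_vox) * 10.0,
                                 np.zeros(n_vox), np.zeros(n_vox)])
    return SourceGrid(positions=positions, inside_mask=np.ones(n_vox, bool),
                      atlas_labels=np.zeros(n_vox, int), spacing=10.0,
                      shape=(n_vox, 1, 1))


class TestSphereForwardModel:
    def test_radial_dipole_is_silent(self, anatomy):
        head, _ = anatomy
        pos = np.array([30.0, 20.0, 10.0])
        radial = pos / np.linalg.norm(pos)
        b = dipole_field(head, pos, radial)
        tangential = np.cross([0, 0, 1.0], radial)
        b_tan = dipole_field(head, pos, tangential / np.linalg.norm(tangential))
        assert np.max(np.abs(b)) < 1e-8 * np.max(np.abs(b_tan))

    def test_linearity_in_moment(self, anatomy):
        head, _ = anatomy
        pos = np.array([-30.0, 10.0, 25.0])
        q = np.array([0.0, 1.0, 0.0])
        assert np.allclose(dipole_field(head, pos, 2 * q),
                           2 * dipole_field(head, pos, q), rtol=1e-12)

    def test_field_magnitude_decays_with_sensor_distance(self):
        """Along a radial line of sensors above a tangential dipole the
        field magnitude falls off monotonically."""
        from betalat.core import HeadModel

        radii = np.linspace(0.11, 0.30, 10)
        positions = np.column_stack([np.zeros(10), np.zeros(10), radii])
        orient = np.tile([0.0, 1.0, 0.0], (10, 1))
        head = HeadModel(sphere_center=np.zeros(3), sensor_positions=positions,
                         sensor_orientations=orient)
        b = dipole_field(head, np.array([0.0, 20.0, 40.0]), np.array([1.0, 0, 0]))
        mags = np.abs(b)
        assert np.all(np.diff(mags) < 0)

    def test_center_dipole_rejected(self, anatomy):
        head, _ = anatomy
        with pytest.raises(InvalidParameterError):
            dipole_field(head, np.zeros(3), np.array([1.0, 0, 0]))

    def test_leadfield_radial_column_silence(self, anatomy):
        head, grid = anatomy
        lf = sphere_leadfield(head, grid)
        inside = grid.inside_indices
        rng = np.random.default_rng(0)
        for v in rng.choice(inside.size, 10, replace=False):
            pos = grid.positions[inside[v]]
            if np.linalg.norm(pos) < 1e-9:
                continue
            g3 = lf.voxel_gain(int(v))
            radial = pos / np.linalg.norm(pos)
            tan_norm = np.linalg.norm(g3, "fro")
            assert np.linalg.norm(g3 @ radial) < 1e-8 * tan_norm


class TestDICSFilter:
    def test_unit_gain_constraint(self, anatomy):
        head, grid = anatomy
        ep, _ = erd_epochs(head, grid, seed=1, n_trials=10)
        base, act = epoch_windows(ep)
        csd = spectral.combine_csd(multitaper_csd(base, ep.sfreq),
                                   multitaper_csd(act, ep.sfreq))
        lf = sphere_leadfield(head, grid)
        filt = dics_common_filter(csd, lf, 0.1)
        for v in range(0, lf.n_inside, 25):
            l = lf.voxel_gain(v) @ filt.orientations[v]
            if not np.any(l):
                continue
            assert filt.weights[v] @ l == pytest.approx(1.0, abs=1e-8)

    def test_matched_filter_with_identity_csd(self):
        """With C = I and a fixed orientation the minimum-variance filter is
        the matched filter w = l / |l|^2."""
        rng = np.random.default_rng(4)
        gain = np.zeros((3, 6))
        l0 = rng.standard_normal(3)
        gain[:, 0] = l0  # voxel 0, x-orientation dominates
        gain[:, 1] = 1e-12 * rng.standard_normal(3)
        gain[:, 2] = 1e-12 * rng.standard_normal(3)
        gain[:, 3:] = rng.standard_normal((3, 3))
        lf = LeadField(gain=gain, grid=toy_grid(2))
        filt = dics_common_filter(toy_csd(np.eye(3)), lf, lambda_frac=0.0)
        w_expected = l0 / (l0 @ l0)
        assert np.allclose(np.abs(filt.weights[0]), np.abs(w_expected), atol=1e-8)

    def test_brute_force_equivalence_on_toy(self):
        """3-sensor/2-voxel toy: weights, orientations and power match a
        direct implementation of the constrained minimum-variance formula
        to 1e-10."""
        rng = np.random.default_rng(7)
        gain = rng.standard_normal((3, 6))
        c = rng.standard_normal((3, 3))
        c = c @ c.T + 3 * np.eye(3)
        lam = 0.1
        lf = LeadField(gain=gain, grid=toy_grid(2))
        filt = dics_common_filter(toy_csd(c), lf, lam)
        c_r = c + lam * np.trace(c) / 3 * np.eye(3)
        ci = np.linalg.inv(c_r)
        for v in range(2):
            l3 = gain[:, 3 * v : 3 * v + 3]
            evals, evecs = np.linalg.eigh(l3.T @ ci @ l3)
            q = evecs[:, 0]
            if q[np.argmax(np.abs(q))] < 0:
                q = -q
            l = l3 @ q
            w = ci @ l / (l @ ci @ l)
            assert np.allclose(filt.orientations[v], q, atol=1e-10)
            assert np.allclose(filt.weights[v], w, atol=1e-10)
            p = filt.weights[v] @ c @ filt.weights[v]
            assert p == pytest.approx(w @ c @ w, abs=1e-10)

    def test_lambda_regularizes_singular_csd(self):
        rank1 = np.outer([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        gain = np.random.default_rng(1).standard_normal((3, 3))
        lf = LeadField(gain=gain, grid=toy_grid(1))
        from betalat import NumericFailureError

        with pytest.raises(NumericFailureError):
            dics_common_filter(toy_csd(rank1), lf, lambda_frac=0.0)
        filt = dics_common_filter(toy_csd(rank1), lf, lambda_frac=0.1)
        assert np.all(np.isfinite(filt.weights))


class TestSourcePower:
    def test_identity_csd_gives_weight_norms(self):
        rng = np.random.default_rng(2)
        gain = rng.standard_normal((3, 6))
        lf = LeadField(gain=gain, grid=toy_grid(2))
        filt = dics_common_filter(toy_csd(np.eye(3) * 2.0), lf, 0.1)
        from betalat import source_power

        p = source_power(filt, toy_csd(np.eye(3)))
        assert np.allclose(p[0], np.sum(filt.weights**2, axis=1), rtol=1e-12)

    def test_power_scales_linearly_with_csd(self):
        rng = np.random.default_rng(3)
        gain = rng.standard_normal((3, 6))
        c = rng.standard_normal((3, 3))
        c = c @ c.T + np.eye(3)
        lf = LeadField(gain=gain, grid=toy_grid(2))
        filt = dics_common_filter(toy_csd(c), lf, 0.1)
        from betalat import source_power

        p1 = source_power(filt, toy_csd(c))
        p5 = source_power(filt, toy_csd(5 * c))
        assert np.allclose(p5, 5 * p1, rtol=1e-12)

    def test_peak_at_simulated_source(self, anatomy):
        head, grid = anatomy
        vox = source_voxel(grid, "left")
        ep, _ = erd_epochs(head, grid, ratio=0.6, seed=5, n_trials=40)
        base, act = epoch_windows(ep)
        cb = multitaper_csd(base, ep.sfreq)
        ca = multitaper_csd(act, ep.sfreq)
        lf = sphere_leadfield(head, grid)
        filt = dics_common_filter(spectral.combine_csd(cb, ca), lf, 0.1)
        pc = percent_change_map(condition_power(filt, cb, ca))
        peak = np.argmin(np.where(pc.mask, pc.values, np.inf))
        dist = np.linalg.norm(grid.positions[peak] - grid.positions[vox])
        assert dist <= grid.spacing

    def test_percent_change_signs(self, anatomy):
        """ERD gives ~ratio^2 - 1 at the source; swapped conditions flip it."""
        head, grid = anatomy
        vox = source_voxel(grid, "left")
        ep, _ = erd_epochs(head, grid, ratio=0.6, seed=6, n_trials=30,
                           noise_sd=1e-14, background_sd=0.0)
        base, act = epoch_windows(ep)
        cb = multitaper_csd(base, ep.sfreq)
        ca = multitaper_csd(act, ep.sfreq)
        lf = sphere_leadfield(head, grid)
        filt = dics_common_filter(spectral.combine_csd(cb, ca), lf, 0.1)
        power = condition_power(filt, cb, ca)
        pc = percent_change_map(power)
        assert pc.values[vox] == pytest.approx(-64.0, abs=3.0)
        swapped = SourcePowerMap(baseline_trials=power.active_trials,
                                 active_trials=power.baseline_trials,
                                 grid=grid)
        pc_sw = percent_change_map(swapped)
        assert pc_sw.values[vox] > 0
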