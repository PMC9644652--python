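"""Synthetic MEG/fMRI test-bed with known lateralization ground truth.

Generates (i) a toy spherical head with magnetometers on the upper
hemisphere and a cubic source grid carrying mirrored left/right pseudo-atlas
labels, (ii) stimulus-locked sensor epochs containing oscillatory dipole
sources whose amplitude drops (event-related desynchronization, ERD) or
rises during a post-stimulus window, and (iii) fMRI-like t-maps with
Gaussian activation blobs. Everything is deterministic under a seed.

The default effect structure emulates a covert verb-generation experiment:
beta-band (around 24 Hz) sources in left-hemisphere language regions lose
roughly 20% of their oscillatory amplitude between 0.3 and 1.0 s after
stimulus onset relative to a pre-stimulus baseline (amplitude ratio 0.89,
i.e. a ~21% power decrease), matching the decrement range observed in
healthy speakers; an optional contralateral source with ratio > 1 models
the power increase seen over the non-dominant hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import beamformer
from .core import (
    HeadModel,
    InvalidParameterError,
    SensorEpochs,
    SourceGrid,
    SourceStatMap,
)

WADA_CATEGORIES = ("L", "R", "Bil")

HEAD_RADIUS_M = 0.09
SENSOR_RADIUS_M = 0.12


def _hemisphere_sensors(n_chan: int) -> np.ndarray:
    """Sensor unit-directions on the upper hemisphere, mirror-symmetric in x.

    Sensors are laid out on rings of constant polar angle with even, half-step
    offset azimuthal spacing, which makes the layout exactly symmetric under
    x -> -x; an odd remainder goes to the vertex.
    """
    ring_theta = np.deg2rad([15.0, 35.0, 55.0, 75.0])
    w = np.sin(ring_theta)
    n_odd = n_chan % 2
    n_even = n_chan - n_odd
    counts = np.maximum(2, 2 * np.round(n_even * w / (2 * w.sum())).astype(int))
    while counts.sum() > n_even:
        counts[np.argmax(counts)] -= 2
    while counts.sum() < n_even:
        counts[np.argmin(counts)] += 2
    dirs = []
    if n_odd:
        dirs.append([0.0, 0.0, 1.0])
    for theta, m in zip(ring_theta, counts):
        phi = (np.arange(m) + 0.5) * 2 * np.pi / m
        dirs.extend(
            np.column_stack([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.full(m, np.cos(theta)),
            ])
        )
    return np.asarray(dirs)


def make_toy_anatomy(
    n_chan: int = 64,
    grid_spacing: float = 10.0,
    seed: int = 0,
    head_radius: float = HEAD_RADIUS_M,
    sensor_radius: float = SENSOR_RADIUS_M,
) -> tuple[HeadModel, SourceGrid]:
    """Build a spherical head model and a mirrored, labelled source grid.

    The grid covers the sphere at ``grid_spacing`` mm resolution; points
    whose radius is below ``head_radius - spacing/2`` are flagged inside.
    Inside points off the midsagittal plane are partitioned into 18
    pseudo-regions (9 per hemisphere, terciles of y crossed with terciles of
    z) that are exact mirror images across x = 0: left labels 1-9 map to
    right labels 10-18 at the reflected position.
    """
    if n_chan < 8:
        raise InvalidParameterError("need at least 8 channels")
    if grid_spacing <= 0:
        raise InvalidParameterError("grid spacing must be positive")
    del seed  # layout is deterministic; kept for interface stability
    dirs = _hemisphere_sensors(n_chan)
    head = HeadModel(
        sphere_center=np.zeros(3),
        sensor_positions=sensor_radius * dirs,
        sensor_orientations=dirs,
    )
    r_mm = head_radius * 1000.0
    n_side = int(np.floor(r_mm / grid_spacing))
    coords = grid_spacing * np.arange(-n_side, n_side + 1)
    xs, ys, zs = np.meshgrid(coords, coords, coords, indexing="ij")
    positions = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    radius = np.linalg.norm(positions, axis=1)
    inside = radius < (r_mm - grid_spacing / 2.0)
    labels = np.zeros(positions.shape[0], dtype=int)
    off_mid = inside & (np.abs(positions[:, 0]) >= grid_spacing / 2.0)
    edges = np.array([-r_mm / 3.0, r_mm / 3.0])
    iy = np.digitize(positions[:, 1], edges)
    iz = np.digitize(positions[:, 2], edges)
    region = iy * 3 + iz  # 0..8, invariant under x -> -x
    labels[off_mid] = np.where(positions[off_mid, 0] < 0, 1 + region[off_mid],
                               10 + region[off_mid])
    grid = SourceGrid(
        positions=positions,
        inside_mask=inside,
        atlas_labels=labels,
        spacing=float(grid_spacing),
        shape=(coords.size, coords.size, coords.size),
    )
    return head, grid


#: Toy atlas groupings mimicking the three language ROI pairs: an
#: anterior-superior "inferior frontal" patch, a two-region temporo-parietal
#: patch and a two-region inferior temporal patch. Values are
#: (left_labels, right_labels).
TOY_ROI_LABELS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "IFG": ((9,), (18,)),
    "WA": ((6, 8), (15, 17)),
    "TIMP": ((1, 2), (10, 11)),
}


@dataclass(frozen=True)
class SourceSpec:
    """One oscillatory dipole: where, at which carrier frequency, how strong
    at baseline (A·m), and by which amplitude ratio the active window scales
    it (< 1 desynchronization, > 1 synchronization)."""

    grid_index: int
    freq: float = 24.0
    amplitude: float = 50e-9
    ratio: float = 0.89


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic subject's recording."""

    n_trials: int = 160
    sfreq: float = 1017.25
    epoch_window: tuple[float, float] = (-1.0, 1.5)
    sources: tuple[SourceSpec, ...] = ()
    erd_window: tuple[float, float] = (0.3, 1.0)
    noise_sd: float = 2e-13  # white sensor noise, tesla
    background_sd: float = 1e-13  # 1/f background, tesla RMS
    background_exponent: float = 1.0
    ramp: float = 0.05  # s, raised-cosine ERD edge
    seed: int = 0


def _tangential_orientation(pos_mm: np.ndarray) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere at ``pos_mm``."""
    r_hat = pos_mm / np.linalg.norm(pos_mm)
    t = np.cross([0.0, 0.0, 1.0], r_hat)
    if np.linalg.norm(t) < np.sin(np.deg2rad(5.0)):
        t = np.cross([1.0, 0.0, 0.0], r_hat)
    return t / np.linalg.norm(t)


def _erd_envelope(times: np.ndarray, ratio: float, window: tuple[float, float],
                  ramp: float) -> np.ndarray:
    """Amplitude envelope: 1 outside the active window, ``ratio`` inside,
    with raised-cosine transitions of length ``ramp`` to avoid spectral
    splatter. The ramps lie just outside the window so the plateau spans
    exactly [t0, t1]."""
    t0, t1 = window
    rise = np.clip((times - (t0 - ramp)) / ramp, 0.0, 1.0)
    fall = np.clip((times - t1) / ramp, 0.0, 1.0)
    blend_in = 0.5 - 0.5 * np.cos(np.pi * rise)
    blend_out = 0.5 - 0.5 * np.cos(np.pi * fall)
    env = 1.0 + (ratio - 1.0) * blend_in + (1.0 - ratio) * blend_out
    return env


def _one_over_f_noise(rng: np.random.Generator, n_trials: int, n_chan: int,
                      n_samp: int, sfreq: float, exponent: float,
                      sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free RMS ``sd``."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_trials, n_chan, freqs.size))
            + 1j * rng.standard_normal((n_trials, n_chan, freqs.size))) * shaping
    noise = np.fft.irfft(spec, n=n_samp, axis=-1)
    rms = np.sqrt(np.mean(noise**2))
    if rms > 0:
        noise *= sd / rms
    return noise


def simulate_epochs(cfg: SimulationConfig, head: HeadModel,
                    grid: SourceGrid) -> SensorEpochs:
    """Project oscillatory dipoles through the spherical forward model.

    Each trial is the sum of the configured sources (trial-wise random
    carrier phase, tangential orientation, ERD envelope), a 1/f background
    and white sensor noise.
    """
    rng = np.random.default_rng(cfg.seed)
    t0, t1 = cfg.epoch_window
    n_samp = int(round((t1 - t0) * cfg.sfreq)) + 1
    times = t0 + np.arange(n_samp) / cfg.sfreq
    n_chan = head.n_chan
    data = np.zeros((cfg.n_trials, n_chan, n_samp))
    for spec in cfg.sources:
        if not grid.inside_mask[spec.grid_index]:
            raise InvalidParameterError(
                f"source grid index {spec.grid_index} is outside the brain")
        pos = grid.positions[spec.grid_index]
        ori = _tangential_orientation(pos)
        gain = beamformer.dipole_field(head, pos, ori)  # (n_chan,)
        env = _erd_envelope(times, spec.ratio, cfg.erd_window, cfg.ramp)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_trials)
        carrier = np.cos(2.0 * np.pi * spec.freq * times[None, :] + phases[:, None])
        sig = spec.amplitude * env[None, :] * carrier  # (n_trials, n_samp)
        data += gain[None, :, None] * sig[:, None, :]
    if cfg.background_sd > 0:
        data += _one_over_f_noise(rng, cfg.n_trials, n_chan, n_samp, cfg.sfreq,
                                  cfg.background_exponent, cfg.background_sd)
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)
    return SensorEpochs(data=data, times=times, sfreq=cfg.sfreq, head=head)


def simulate_tmap(
    grid: SourceGrid,
    blob_spec: list[tuple[int, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SourceStatMap:
    """fMRI-like t-map: Gaussian-profile blobs centred on atlas regions.

    ``blob_spec`` is a list of ``(atlas_label, peak_t, sd_mm)``; each blob is
    ``peak_t * exp(-d^2 / (2 sd_mm^2))`` around the region centroid. I.i.d.
    Gaussian noise of scale ``noise_sd`` is added on inside voxels.
    """
    rng = np.random.default_rng(seed)
    values = np.zeros(grid.n_grid)
    for label, peak_t, sd_mm in blob_spec:
        center = grid.label_centroid(int(label))  # raises on unknown label
        d2 = np.sum((grid.positions - center) ** 2, axis=1)
        values += peak_t * np.exp(-d2 / (2.0 * sd_mm**2))
    mask = grid.inside_mask.copy()
    values[~mask] = 0.0
    if noise_sd > 0:
        values[mask] += noise_sd * rng.standard_normal(int(mask.sum()))
    return SourceStatMap(values=values, mask=mask, grid=grid,
                         info={"kind": "simulated_tmap", "seed": seed})


def simulate_wada(category: str) -> str:
    """Validate and return a Wada-test dominance category (L, R or Bil)."""
    if category not in WADA_CATEGORIES:
        raise InvalidParameterError(
            f"unknown Wada category {category!r}; expected one of {WADA_CATEGORIES}")
    return category
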