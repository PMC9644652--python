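"""Time-frequency decomposition and cross-spectral density estimation.

Two spectral estimators feed the pipeline:

* a Morlet-wavelet time-frequency transform (default 1-45 Hz in 1-Hz steps,
  five cycles) used for the exploratory sensor-level view of event-related
  desynchronization, expressed as relative power change against a
  pre-stimulus baseline;
* a multitaper (DPSS) cross-spectral density at a single analysis frequency
  (default 24 Hz with +-11 Hz spectral smoothing) that drives the DICS
  beamformer. Tapering is applied per trial segment and cross-spectra are
  averaged over tapers and trials, which has the same expectation as
  tapering a concatenated trial series but avoids boundary artifacts.

The taper count follows the standard rule K = floor(2 T W) - 1 for segment
duration T and half-bandwidth W; with the default 0.7-s segments and
W = 11 Hz this gives 14 tapers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .core import InvalidInputError, InvalidParameterError, SensorEpochs

DEFAULT_FREQS = np.arange(1.0, 46.0)
DEFAULT_BASELINE = (-0.7, 0.0)
DEFAULT_ACTIVE = (0.3, 1.0)


@dataclass
class TFR:
    """Trial-averaged wavelet power: (n_chan, n_freq, n_time).

    ``valid`` marks the time-frequency cells whose wavelet support fits
    inside the epoch; invalid cells hold NaN rather than zero-filled edges.
    ``mode`` is ``"absolute"`` or ``"relative-change"``.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray  # (n_freq, n_time) bool
    mode: str = "absolute"
    sfreq: float = 0.0
    n_cycles: float = 5.0


def morlet_tfr(epochs: SensorEpochs, freqs=DEFAULT_FREQS, n_cycles: float = 5.0) -> TFR:
    """Trial-averaged Morlet wavelet power of sensor epochs.

    Time samples closer to either epoch edge than half the nominal wavelet
    duration (``n_cycles / (2 f)``) are flagged invalid.
    """
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, float)
    power = tfr_array_morlet(
        epochs.data, sfreq=epochs.sfreq, freqs=freqs, n_cycles=n_cycles,
        output="avg_power", zero_mean=True, verbose="error",
    )
    times = epochs.times
    half = n_cycles / (2.0 * freqs)  # s
    valid = ((times[None, :] - times[0]) >= half[:, None]) & (
        (times[-1] - times[None, :]) >= half[:, None]
    )
    power = power.astype(float)
    power[:, ~valid] = np.nan
    return TFR(power=power, freqs=freqs, times=times, valid=valid,
               mode="absolute", sfreq=epochs.sfreq, n_cycles=n_cycles)


def relative_power_change(tfr: TFR, baseline_window: tuple[float, float] = DEFAULT_BASELINE) -> TFR:
    """Per-cell relative change ``(P - <P>_baseline) / <P>_baseline``.

    Cells whose channel x frequency baseline mean is zero are flagged
    invalid (NaN) instead of dividing by zero.
    """
    if tfr.mode != "absolute":
        raise InvalidInputError("relative change requires an absolute-power TFR")
    sel = (tfr.times >= baseline_window[0]) & (tfr.times < baseline_window[1])
    if not sel.any():
        raise InvalidInputError("baseline window contains no time samples")
    base_valid = tfr.valid[:, sel]
    if not base_valid.any(axis=1).all():
        raise InvalidInputError("baseline window lies outside valid wavelet support "
                                "for at least one frequency")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(tfr.power[:, :, sel], axis=2)  # (n_chan, n_freq)
    rel = np.empty_like(tfr.power)
    zero = ~(base > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (tfr.power - base[:, :, None]) / base[:, :, None]
    rel[zero, :] = np.nan
    return TFR(power=rel, freqs=tfr.freqs, times=tfr.times, valid=tfr.valid.copy(),
               mode="relative-change", sfreq=tfr.sfreq, n_cycles=tfr.n_cycles)


def epoch_windows(
    epochs: SensorEpochs,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    active: tuple[float, float] = DEFAULT_ACTIVE,
    demean: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut trials into equal-duration baseline and active segments.

    Defaults follow the analysis contrast: baseline 0-700 ms pre-stimulus,
    active 300-1000 ms post-stimulus. Both segments get exactly
    ``round(duration * sfreq)`` samples so the spectral estimates are
    directly comparable; each segment is demeaned with its own mean.
    """
    if not np.isclose(baseline[1] - baseline[0], active[1] - active[0]):
        raise InvalidParameterError("baseline and active windows must have equal duration")
    n = int(round((baseline[1] - baseline[0]) * epochs.sfreq))
    if n < 2:
        raise InvalidInputError("windows too short for the sampling rate")
    i_base = int(np.searchsorted(epochs.times, baseline[0] - 1e-9))
    i_act = int(np.searchsorted(epochs.times, active[0] - 1e-9))
    if epochs.times[0] > baseline[0] + 1e-9 or i_act + n > epochs.times.size:
        raise InvalidInputError("epochs do not cover the requested windows")
    base = epochs.data[:, :, i_base : i_base + n].copy()
    act = epochs.data[:, :, i_act : i_act + n].copy()
    if demean:
        base -= base.mean(axis=2, keepdims=True)
        act -= act.mean(axis=2, keepdims=True)
    return base, act


@dataclass
class CrossSpectrum:
    """Multitaper cross-spectral density at one analysis frequency.

    ``csd`` is the Hermitian trial-average; ``per_trial_csd`` keeps the
    single-trial matrices needed for trialwise beamformer statistics. The
    diagonal is normalised to band-limited signal variance: a sinusoid of
    amplitude A at the centre frequency yields A^2 / 2.
    """

    csd: np.ndarray  # (n_chan, n_chan) complex
    per_trial_csd: np.ndarray  # (n_trials, n_chan, n_chan) complex
    center_freq: float
    halfbandwidth: float
    n_tapers: int
    condition: str = ""

    @property
    def n_trials(self) -> int:
        return self.per_trial_csd.shape[0]


def n_tapers_for(duration: float, halfbandwidth: float) -> int:
    """K = floor(2 T W) - 1 (the conventional DPSS taper count)."""
    return int(np.floor(2.0 * duration * halfbandwidth)) - 1


def multitaper_csd(
    segments: np.ndarray,
    sfreq: float,
    center_freq: float = 24.0,
    halfbandwidth: float = 11.0,
    condition: str = "",
) -> CrossSpectrum:
    """Per-trial and trial-averaged DPSS cross-spectral density.

    ``segments`` is (n_trials, n_chan, n_samples). Fourier coefficients are
    evaluated at the frequency bin of the next-power-of-two grid nearest to
    ``center_freq`` (by direct DFT at that single bin).
    """
    segments = np.asarray(segments, float)
    if segments.ndim != 3:
        raise InvalidInputError("segments must be (n_trials, n_chan, n_samples)")
    n_trials, n_chan, n_samp = segments.shape
    duration = n_samp / sfreq
    if duration <= 1.0 / halfbandwidth:
        raise InvalidParameterError("segment duration must exceed 1/halfbandwidth")
    k = n_tapers_for(duration, halfbandwidth)
    if k < 1:
        raise InvalidParameterError("time-bandwidth product too small for a single taper")
    nw = duration * halfbandwidth
    tapers = dpss(n_samp, NW=nw, Kmax=k)  # (k, n_samp), unit energy
    nfft = 1 << int(np.ceil(np.log2(n_samp)))
    bins = np.fft.fftfreq(nfft, 1.0 / sfreq)[: nfft // 2]
    f_bin = bins[np.argmin(np.abs(bins - center_freq))]
    phase = np.exp(-2j * np.pi * f_bin * np.arange(n_samp) / sfreq)
    # (n_trials, k, n_chan) tapered Fourier coefficients at the single bin
    coeff = np.einsum("tcn,kn,n->tkc", segments, tapers, phase, optimize=True)
    # normalisation: a centre-frequency sinusoid of amplitude A gives A^2/2
    taper_dc = tapers.sum(axis=1)
    scale = 2.0 / np.sum(taper_dc**2)
    per_trial = scale * np.einsum("tkc,tkd->tcd", coeff, np.conj(coeff), optimize=True)
    csd = per_trial.mean(axis=0)
    return CrossSpectrum(csd=csd, per_trial_csd=per_trial, center_freq=float(f_bin),
                         halfbandwidth=halfbandwidth, n_tapers=k, condition=condition)


def combine_csd(baseline: CrossSpectrum, active: CrossSpectrum) -> CrossSpectrum:
    """Pooled-condition CSD: the trial-count-weighted mean of the condition
    CSDs (used to build the common DICS filter)."""
    if baseline.csd.shape != active.csd.shape:
        raise InvalidInputError("condition CSDs have different channel counts")
    n_b, n_a = baseline.n_trials, active.n_trials
    csd = (n_b * baseline.csd + n_a * active.csd) / (n_b + n_a)
    per_trial = np.concatenate([baseline.per_trial_csd, active.per_trial_csd], axis=0)
    return CrossSpectrum(csd=csd, per_trial_csd=per_trial,
                         center_freq=baseline.center_freq,
                         halfbandwidth=baseline.halfbandwidth,
                         n_tapers=baseline.n_tapers, condition="combined")


def csd_band_power(csd: CrossSpectrum) -> np.ndarray:
    """Per-channel band-limited variance estimate (the real CSD diagonal)."""
    return np.real(np.diag(csd.csd))


@lru_cache(maxsize=8)
def _wavelet_response(sfreq: float, freqs_key: tuple, n_cycles: float,
                      duration: float) -> np.ndarray:
    """R[j, i]: power reported at wavelet row ``freqs[i]`` for a
    unit-amplitude sinusoid at probe frequency ``freqs[j]`` (mid-epoch)."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs_key)
    n_t = int(round(duration * sfreq))
    t = np.arange(n_t) / sfreq
    probes = np.cos(2 * np.pi * freqs[:, None] * t[None, :])  # (n_probe, n_t)
    power = tfr_array_morlet(probes[None], sfreq=sfreq, freqs=freqs,
                             n_cycles=n_cycles, output="avg_power",
                             verbose="error")
    return power[:, :, n_t // 2]  # (n_probe, n_freq)


def tfr_band_power(tfr: TFR, fmin: float, fmax: float,
                   time_window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-channel band power integrated over ``[fmin, fmax]``.

    Each frequency row is converted to a spectral density by dividing by the
    wavelet's own peak response and equivalent-noise bandwidth (both
    computed from the transform's response to unit sinusoids), then summed
    over the band. Units match :func:`csd_band_power`: a sinusoid of
    amplitude A inside the band integrates to A^2 / 2.
    """
    if tfr.mode != "absolute":
        raise InvalidInputError("band power requires an absolute-power TFR")
    span = float(tfr.times[-1] - tfr.times[0])
    resp = _wavelet_response(tfr.sfreq, tuple(tfr.freqs), tfr.n_cycles,
                             min(span, 4.0))
    peak = np.diag(resp)  # row response to its own frequency
    enbw = resp.sum(axis=0) / peak  # bins (grid steps) per row
    band = (tfr.freqs >= fmin) & (tfr.freqs <= fmax)
    sel = np.ones_like(tfr.times, bool)
    if time_window is not None:
        sel = (tfr.times >= time_window[0]) & (tfr.times < time_window[1])
    p = tfr.power[:, band][:, :, sel]
    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(p, axis=2)  # (n_chan, n_band)
    dens = mean_t / (peak[band] * enbw[band])[None, :]
    return 0.5 * np.nansum(dens, axis=1)
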