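"""Hilbert filter-bank time–frequency analysis of the virtual-sensor series.

The induced gamma response is summarized by one number per contrast level:
trials are decomposed with a 30–80 Hz filter bank (2-Hz spaced centers,
±4 Hz pass-bands, zero-phase Butterworth), the analytic-signal amplitude
envelope is averaged over trials and expressed as percent change from the
rest-trial baseline, the 1-s trial is split into four 250-ms windows (one per
checkerboard reversal), the time-averaged percent change is maximized over
frequency within each window, and the four window maxima are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .megforward import EDGE_TRIM_S, FILTER_PAD_S

#: filter-bank center frequencies (Hz) and half bandwidth
DEFAULT_FREQS = np.arange(30.0, 81.0, 2.0)
HALF_BANDWIDTH = 4.0


@dataclass
class TimeFrequencyEnvelope:
    """Trial-averaged percent-change envelope on a (frequency, time) grid."""

    values: np.ndarray        # (n_freqs, n_times) percent change from baseline
    freqs: np.ndarray         # Hz
    rate: float               # Hz
    baseline_mean: np.ndarray  # (n_freqs,) rest-envelope amplitude per bin

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFR contains non-finite values")


def _edge_mask(n_times: int, rate: float) -> np.ndarray:
    trim = int(round(EDGE_TRIM_S * rate))
    m = np.zeros(n_times, bool)
    m[trim:n_times - trim] = True
    return m


def hilbert_envelope(ts: np.ndarray, rate: float, freqs=None,
                     half_bw: float = HALF_BANDWIDTH, order: int = 4
                     ) -> np.ndarray:
    """Per-trial amplitude envelopes over a frequency grid.

    ``ts`` is (trials, time) or (time,).  Each trial is demeaned, tapered
    over its first/last 50 ms (the same edge samples later excluded from
    time averages, so retained samples are undistorted), zero-padded by
    200 ms, band-pass filtered (zero-phase) per center frequency, and the
    magnitude of the analytic signal is taken.  The taper removes the
    trial-edge discontinuity that would otherwise ring through narrow bands
    into the trial interior.  Returns (trials, n_freqs, time).
    """
    ts = np.atleast_2d(np.asarray(ts, float))
    if not np.all(np.isfinite(ts)):
        raise ValueError("input contains non-finite samples")
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, float)
    if rate < 2.5 * freqs.max():
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {freqs.max()} Hz band")
    pad = int(round(FILTER_PAD_S * rate))
    ramp = int(round(EDGE_TRIM_S * rate))
    taper = np.ones(ts.shape[1])
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    taper[:ramp] = edge
    taper[-ramp:] = edge[::-1]
    ts = (ts - ts.mean(axis=1, keepdims=True)) * taper
    padded = np.pad(ts, [(0, 0), (pad, pad)], mode="constant")
    out = np.empty((ts.shape[0], len(freqs), ts.shape[1]))
    for k, f0 in enumerate(freqs):
        sos = signal.butter(order, (f0 - half_bw, f0 + half_bw),
                            btype="bandpass", fs=rate, output="sos")
        filt = signal.sosfiltfilt(sos, padded, axis=-1)
        out[:, k] = np.abs(signal.hilbert(filt, axis=-1))[:, pad:-pad]
    return out


def percent_change_tfr(stim_env: np.ndarray, rest_env: np.ndarray,
                       rate: float, freqs=None) -> TimeFrequencyEnvelope:
    """Trial-averaged stimulus envelope as percent change from rest.

    The subtracted reference is the trial-averaged rest envelope *profile*
    (per frequency and time sample), normalized by its time average per bin
    (edge samples excluded).  For stationary rest activity the profile is
    flat and this reduces to the plain scalar-baseline percent change; the
    time-resolved subtraction additionally cancels the deterministic
    envelope shape that per-trial narrowband filtering imprints identically
    on stimulus and rest trials.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    stim_env = np.asarray(stim_env, float)
    rest_env = np.asarray(rest_env, float)
    if stim_env.shape[0] == 0 or rest_env.shape[0] == 0:
        raise ValueError("need at least one stimulus and one rest trial")
    tmask = _edge_mask(rest_env.shape[-1], rate)
    profile = rest_env.mean(axis=0)            # (n_freqs, n_times)
    baseline = profile[:, tmask].mean(axis=1)  # (n_freqs,)
    if np.any(baseline <= 0):
        raise ValueError("zero rest baseline in at least one frequency bin")
    values = 100.0 * (stim_env.mean(axis=0) - profile) / baseline[:, None]
    return TimeFrequencyEnvelope(values, np.asarray(freqs, float), rate,
                                 baseline)


def peak_gamma(tfr: TimeFrequencyEnvelope, reversal_period: float = 0.25,
               fixed_frequency: bool = False,
               baseline_floor: float = 0.1):
    """Reversal-windowed peak gamma change.

    Splits the trial into ``duration/reversal_period`` windows (four for a
    1-s trial), averages percent change over time within each window, takes
    the maximum over the frequency grid per window (signed), and returns the
    mean of the window maxima plus the modal peak frequency.

    Bins whose rest baseline is below ``baseline_floor`` times the largest
    bin baseline are excluded from the maxima: a percent change over an
    (effectively) empty baseline is numerically meaningless.  With a
    broadband rest spectrum every bin passes the floor.

    With ``fixed_frequency=True`` a single peak frequency is chosen from the
    window-averaged spectra and all windows are read at that bin.
    """
    valid = tfr.baseline_mean >= baseline_floor * tfr.baseline_mean.max()
    if not valid.any():
        raise ValueError("no frequency bin has a usable baseline")
    n_times = tfr.values.shape[1]
    win = int(round(reversal_period * tfr.rate))
    n_win = n_times // win
    if n_win * win != n_times:
        raise ValueError("trial length not divisible by the reversal period")
    tmask = _edge_mask(n_times, tfr.rate)
    spectra = np.empty((n_win, len(tfr.freqs)))
    for k in range(n_win):
        m = tmask[k * win:(k + 1) * win]
        spectra[k] = tfr.values[:, k * win:(k + 1) * win][:, m].mean(axis=1)
    spectra[:, ~valid] = -np.inf
    if fixed_frequency:
        idx = np.full(n_win, int(np.argmax(spectra.mean(axis=0))))
    else:
        idx = np.argmax(spectra, axis=1)
    maxima = spectra[np.arange(n_win), idx]
    freqs, counts = np.unique(tfr.freqs[idx], return_counts=True)
    return float(maxima.mean()), float(freqs[np.argmax(counts)])


def baseline_gamma(rest_env: np.ndarray, rate: float) -> float:
    """Grand-mean 30–80 Hz rest amplitude (trials × frequency × time)."""
    rest_env = np.asarray(rest_env, float)
    if rest_env.shape[0] == 0:
        raise ValueError("need at least one rest trial")
    tmask = _edge_mask(rest_env.shape[-1], rate)
    return float(rest_env[..., tmask].mean())
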