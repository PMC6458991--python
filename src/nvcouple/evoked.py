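"""Visual-evoked-field (VEF) latency analysis.

Stimulus trials are re-epoched around each checkerboard reversal
(−0.04 to 0.21 s), averaged, low-pass filtered at 15 Hz (zero-phase
Butterworth), baseline corrected on the pre-reversal window, and the latency
of the peak absolute deflection in (0, 0.21] s is extracted.  The same code
path serves the sensor-level analysis (a designated posterior sensor average)
and the source-level analysis (the beamformer virtual sensor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

BASELINE_WINDOW = (-0.04, 0.0)
STIMULUS_WINDOW = (0.0, 0.21)


class FlatEvokedError(ValueError):
    """Raised when the averaged evoked response has no defined peak."""


@dataclass
class EvokedEpochs:
    data: np.ndarray   # (epochs, time)
    rate: float
    n_dropped: int = 0  # partial epochs discarded at block/trial edges

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[1]
        return BASELINE_WINDOW[0] + np.arange(n) / self.rate


def epoch_reversals(trials: np.ndarray, rate: float,
                    reversal_times=(0.0, 0.25, 0.5, 0.75)) -> EvokedEpochs:
    """Cut −0.04..0.21 s epochs around each reversal within 1-s trials.

    ``trials`` is (n_trials, time), e.g. the virtual-sensor series or a
    posterior-sensor average.  Epochs that would extend beyond a trial's edge
    (typically the reversal at 0 s, which has no baseline samples) are
    dropped; their count is recorded.
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    if trials.shape[0] == 0:
        raise ValueError("no stimulus trials to epoch")
    pre = int(round(-BASELINE_WINDOW[0] * rate))
    post = int(round(STIMULUS_WINDOW[1] * rate))
    n_time = trials.shape[1]
    epochs, dropped = [], 0
    for rev in reversal_times:
        start = int(round(rev * rate)) - pre
        stop = int(round(rev * rate)) + post  # half-open: 0.25 s -> 150 samples
        if start < 0 or stop > n_time:
            dropped += trials.shape[0]
            continue
        epochs.append(trials[:, start:stop])
    if not epochs:
        raise ValueError("no complete reversal epochs in range")
    return EvokedEpochs(np.concatenate(epochs, axis=0), rate, dropped)


def vef_peak_latency(epochs: EvokedEpochs, lowpass: float = 15.0,
                     min_epochs: int = 10, order: int = 4):
    """Peak latency (ms) and amplitude of the average evoked response.

    Averages over epochs, applies a zero-phase low-pass, subtracts the
    baseline-window mean, and returns the time of maximum |amplitude| in
    (0, 0.21] s.  Ties resolve to the earliest latency.
    """
    if epochs.data.shape[0] < min_epochs:
        raise ValueError(
            f"need at least {min_epochs} epochs, got {epochs.data.shape[0]}")
    avg = epochs.data.mean(axis=0)
    sos = signal.butter(order, lowpass, btype="lowpass", fs=epochs.rate,
                        output="sos")
    pad = min(len(avg) - 1, int(round(0.1 * epochs.rate)))
    filt = signal.sosfiltfilt(sos, np.pad(avg, pad, mode="reflect"))[
        pad:len(avg) + pad]
    t = epochs.times
    base = filt[(t >= BASELINE_WINDOW[0]) & (t <= 0)].mean()
    corrected = filt - base
    post = t > 0
    resp = np.abs(corrected[post])
    scale = np.abs(corrected).max()
    if scale == 0 or resp.max() < 1e-12 * scale or np.ptp(resp) == 0:
        raise FlatEvokedError("no defined evoked peak (flat response)")
    i = int(np.argmax(resp))  # argmax → earliest index on exact ties
    return float(t[post][i] * 1000.0), float(corrected[post][i])


def posterior_sensor_average(epochs_data: np.ndarray, positions: np.ndarray,
                             n_sensors: int = 5) -> np.ndarray:
    """Average the ``n_sensors`` most posterior (lowest y) channels.

    Stands in for the fixed set of posterior occipital sensors used in
    clinical-style sensor-space VEF reads.  ``epochs_data`` is
    (trials, channels, time); returns (trials, time).
    """
    order = np.argsort(positions[:, 1])
    return epochs_data[:, order[:n_sensors], :].mean(axis=1)
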