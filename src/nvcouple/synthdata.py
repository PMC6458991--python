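"""Synthetic MEG/ASL cohort with known ground truth.

Generates everything the pipeline consumes: the pseudorandomized 30-s block
design (5 contrast levels × 4 blocks + 8 rest blocks, 14 min per eye), MEG
sensor epochs containing a gamma-modulated occipital dipole with
reversal-locked evoked transients, dual-echo pulsed-ASL volume series with
block-modulated perfusion and BOLD components, multi-TI difference data from
the kinetic model, and a measurement-level cohort table for group statistics
at full sample size.

Contrast dependence is a Naka–Rushton function (the minimal monotone
saturating form); hemodynamic truth amplitudes are linear in the gamma truth
(intercept + slope × gamma %), so every subject's coupling gradient is known
exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import aslkinetics
from .aslactivation import _condition_boxcars
from .containers import AslSeries, SensorEpochs
from .megforward import HeadModel, SensorArray, hemisphere_array, sphere_leadfield

#: Michelson contrast fractions of the checkerboard
CONTRAST_LEVELS = (0.0625, 0.125, 0.25, 0.5, 1.0)
BLOCK_S = 30.0
N_BLOCKS_PER_CONTRAST = 4
N_REST_BLOCKS = 8
REVERSAL_PERIOD_S = 0.25
TR_S = 2.2
N_PAIRS = 191
EYES = ("left", "right")


# ---------------------------------------------------------------------------
# Contrast response and block schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResponseParams:
    """Naka–Rushton contrast-response parameters.

    response(c) = floor + r_max · c^n / (c^n + c50^n); non-decreasing in c.
    """

    r_max: float
    c50: float
    n_exp: float
    floor: float = 0.0

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not 0 < self.c50 < 1:
            raise ValueError("c50 must lie in (0, 1)")
        if self.n_exp <= 0:
            raise ValueError("n_exp must be positive")


def contrast_response(c, p: ContrastResponseParams):
    """Naka–Rushton response at contrast fraction(s) ``c`` in [0, 1]."""
    c = np.asarray(c, float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("contrast must lie in [0, 1]")
    cn = c ** p.n_exp
    out = p.floor + p.r_max * cn / (cn + p.c50 ** p.n_exp)
    return float(out) if out.ndim == 0 else out


@dataclass
class BlockSchedule:
    """Ordered 30-s blocks for one eye's 14-min run.

    ``entries`` columns: ``condition`` (contrast fraction, or ``"rest"``),
    ``onset`` (s), ``duration`` (s).  The order is a deterministic function
    of (seed, eye); MEG and fMRI of the same subject reuse the same object.
    """

    entries: pd.DataFrame
    eye: str
    seed: int

    @property
    def total_duration(self) -> float:
        return float(self.entries["duration"].sum())

    def stimulus_entries(self) -> pd.DataFrame:
        return self.entries[self.entries["condition"] != "rest"]

    def reversal_times(self) -> np.ndarray:
        """Checkerboard reversal times (s) across all stimulus blocks."""
        out = []
        for _, row in self.stimulus_entries().iterrows():
            out.append(row["onset"]
                       + np.arange(0, row["duration"], REVERSAL_PERIOD_S))
        return np.concatenate(out)


def make_schedule(seed: int, eye: str = "left") -> BlockSchedule:
    """Pseudorandomized block order: 4 blocks per contrast + 8 rest blocks.

    No ordering constraints are imposed beyond the block counts.
    """
    if eye not in EYES:
        raise ValueError(f"eye must be one of {EYES}")
    rng = np.random.default_rng([int(seed), EYES.index(eye)])
    conditions = ([c for c in CONTRAST_LEVELS
                   for _ in range(N_BLOCKS_PER_CONTRAST)]
                  + ["rest"] * N_REST_BLOCKS)
    order = rng.permutation(len(conditions))
    entries = pd.DataFrame({
        "condition": [conditions[i] for i in order],
        "onset": np.arange(len(conditions)) * BLOCK_S,
        "duration": BLOCK_S,
    })
    return BlockSchedule(entries=entries, eye=eye, seed=int(seed))


# ---------------------------------------------------------------------------
# Subject ground truth
# ---------------------------------------------------------------------------

def default_noise() -> dict:
    """Noise levels per modality (the simulated study conditions)."""
    return {
        # raw MEG: additive white sensor noise (T) and broadband source
        # activity (fraction of the baseline gamma amplitude)
        "meg_sensor_sd": 1e-14,
        "meg_source_broadband": 0.5,
        # raw ASL volume noise (signal units; static tissue is ~1000)
        "asl_sd": 2.0,
        # multi-TI difference noise, fraction of the plateau signal (per
        # acquisition, before averaging over repeats)
        "multiti_sd_frac": 0.05,
        # measurement-level noise (per contrast × eye observation)
        "meas_gamma_sd": 4.0,    # % points
        "meas_bold_sd": 0.25,    # % points
        "meas_cbf_sd": 6.0,      # % points
        "meas_baseline_cbf_sd": 4.0,  # ml/100 g/min
    }


@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one synthetic subject."""

    subject: str
    group: str                      # "control" | "patient"
    gamma: ContrastResponseParams   # peak gamma percent change vs contrast
    gamma_peak_freq: float          # Hz
    evoked_latency_ms: float
    evoked_amp: float               # source units (A·m), relative scale
    bold_slope: float               # BOLD % per % gamma change
    bold_intercept: float           # BOLD % at zero gamma change
    cbf_slope: float                # CBF % per % gamma change
    cbf_intercept: float
    baseline_cbf: float             # ml/100 g/min
    arrival_time: float             # s
    eye_gain: dict = field(default_factory=lambda: {"left": 1.0, "right": 1.0})
    source_amp: float = 1e-8        # baseline gamma dipole moment, A·m
    noise: dict = field(default_factory=default_noise)

    def gamma_pct(self, c, eye: str = "left"):
        """Injected peak gamma percent change at contrast ``c`` for ``eye``."""
        return self.eye_gain[eye] * contrast_response(c, self.gamma)

    def bold_pct(self, c, eye: str = "left"):
        return self.bold_intercept + self.bold_slope * self.gamma_pct(c, eye)

    def cbf_pct(self, c, eye: str = "left"):
        return self.cbf_intercept + self.cbf_slope * self.gamma_pct(c, eye)

    def cbf_quant(self, c, eye: str = "left"):
        return self.cbf_pct(c, eye) / 100.0 * self.baseline_cbf

    @property
    def coupling_slope_bold(self) -> float:
        return self.bold_slope

    @property
    def coupling_slope_cbf(self) -> float:
        return self.cbf_slope


#: group-level generative defaults; patients have reduced gamma gain at high
#: contrast (group × contrast interaction), reduced BOLD/CBF through the
#: coupling map, similar-median but more variable coupling slopes, and the
#: baseline-perfusion distributions of the reference cohort.
GROUP_DEFAULTS = {
    "control": dict(gamma_rmax=(40.0, 8.0), gamma_floor=(2.0, 0.5),
                    bold_slope_med=0.03, bold_slope_sigma=0.25,
                    bold_intercept=(0.31, 0.10),
                    cbf_slope_med=1.03, cbf_slope_sigma=0.25,
                    cbf_intercept=(5.08, 1.50),
                    baseline_cbf=(57.7, 21.2)),
    "patient": dict(gamma_rmax=(25.0, 8.0), gamma_floor=(2.0, 0.5),
                    bold_slope_med=0.04, bold_slope_sigma=0.50,
                    bold_intercept=(0.04, 0.15),
                    cbf_slope_med=1.30, cbf_slope_sigma=0.50,
                    cbf_intercept=(1.97, 2.00),
                    baseline_cbf=(52.0, 15.2)),
}


def sample_subject(group: str, subject: str, rng: np.random.Generator
                   ) -> SubjectTruth:
    g = GROUP_DEFAULTS[group]
    rmax = max(5.0, rng.normal(*g["gamma_rmax"]))
    gamma = ContrastResponseParams(
        r_max=rmax,
        c50=float(np.clip(rng.normal(0.25, 0.05), 0.10, 0.50)),
        n_exp=float(np.clip(rng.normal(1.3, 0.2), 0.8, 2.0)),
        floor=max(0.5, rng.normal(*g["gamma_floor"])))
    return SubjectTruth(
        subject=subject, group=group, gamma=gamma,
        gamma_peak_freq=float(np.clip(rng.normal(55.0, 5.0), 40.0, 70.0)),
        evoked_latency_ms=float(rng.normal(120.0, 10.0)),
        evoked_amp=5e-9,
        bold_slope=float(g["bold_slope_med"]
                         * np.exp(rng.normal(0, g["bold_slope_sigma"]))),
        bold_intercept=float(rng.normal(*g["bold_intercept"])),
        cbf_slope=float(g["cbf_slope_med"]
                        * np.exp(rng.normal(0, g["cbf_slope_sigma"]))),
        cbf_intercept=float(rng.normal(*g["cbf_intercept"])),
        baseline_cbf=float(np.clip(rng.normal(*g["baseline_cbf"]), 25, 110)),
        arrival_time=float(np.clip(rng.normal(0.65, 0.08), 0.3, 1.0)),
        eye_gain={"left": 1.0, "right": float(rng.normal(1.0, 0.08))},
    )


def default_cohort(n_controls: int = 10, n_patients: int = 14, seed: int = 0
                   ) -> list[SubjectTruth]:
    """The reference cohort: 10 controls and 14 patients."""
    rng = np.random.default_rng(seed)
    truths = [sample_subject("control", f"ctl{i:02d}", rng)
              for i in range(n_controls)]
    truths += [sample_subject("patient", f"pat{i:02d}", rng)
               for i in range(n_patients)]
    return truths


# ---------------------------------------------------------------------------
# Raw MEG simulation
# ---------------------------------------------------------------------------

DEFAULT_SOURCE_OFFSET = np.array([0.0, -0.05, 0.02])  # m, occipital


def _dominant_orientation(loc, array: SensorArray, head: HeadModel
                          ) -> np.ndarray:
    """SVD-dominant (maximally visible, tangential) dipole orientation.

    Simulated sources are oriented along the direction the sensor array sees
    best — the same single orientation the beamformer's SVD reduction scans,
    so the analysis model matches the generative model.
    """
    from .megforward import reduce_orientation
    _, v = reduce_orientation(sphere_leadfield(loc, array, head))
    return v


def evoked_waveform(t, latency_s: float, amp: float, width_s: float = 0.025
                    ) -> np.ndarray:
    """Gaussian-windowed biphasic evoked transient peaking at ``latency_s``.

    The width keeps the transient's spectrum below the gamma band; the
    delayed rebound lobe is far enough from the main peak not to shift it.
    """
    t = np.asarray(t, float)
    main = np.exp(-0.5 * ((t - latency_s) / width_s) ** 2)
    rebound = np.exp(-0.5 * ((t - latency_s - 0.09) / (1.5 * width_s)) ** 2)
    return amp * (main - 0.5 * rebound)


def simulate_meg(truth: SubjectTruth, schedule: BlockSchedule,
                 array: SensorArray | None = None,
                 head: HeadModel | None = None,
                 seed: int = 0, rate: float = 600.0,
                 trials_per_block: int = 30,
                 source_loc=None, frozen_gamma: bool = False) -> SensorEpochs:
    """Sensor-array epochs for one eye's run.

    Each block contributes ``trials_per_block`` 1-s trials (30 under the
    study conditions).  Stimulus trials carry a gamma oscillation at the
    subject's peak frequency whose amplitude is raised by
    ``1 + gamma_pct(c)/100`` relative to rest, four reversal-locked evoked
    transients, and broadband source activity; everything is projected
    through the spherical-conductor lead field of a fixed tangential
    occipital dipole, with additive white sensor noise.

    ``frozen_gamma=True`` replaces the stochastic narrowband process with a
    fixed-phase tone at the subject's peak frequency, making every stimulus
    trial an exact amplitude scaling of the rest trials — the deterministic
    validation mode in which the full analysis chain recovers injected
    percent changes exactly.
    """
    if rate < 600.0:
        raise ValueError("sampling rate must be >= 600 Hz for an 80-Hz band")
    head = head or HeadModel()
    array = array or hemisphere_array()
    if source_loc is None:
        source_loc = head.center + DEFAULT_SOURCE_OFFSET
    if np.linalg.norm(np.asarray(source_loc) - head.center) >= head.radius:
        raise ValueError("dipole must lie inside the conductor")
    rng = np.random.default_rng([int(seed), 101])
    q = _dominant_orientation(source_loc, array, head)
    gain = sphere_leadfield(source_loc, array, head) @ q  # (channels,)

    n_t = int(round(rate))
    t = np.arange(n_t) / rate
    rev_onsets = np.arange(0.0, 1.0, REVERSAL_PERIOD_S)
    evoked = sum(evoked_waveform(t - r, truth.evoked_latency_ms / 1000.0,
                                 truth.evoked_amp) for r in rev_onsets)

    a0 = truth.source_amp
    bb_sd = truth.noise["meg_source_broadband"] * a0
    sensor_sd = truth.noise["meg_sensor_sd"]
    # induced gamma: a narrowband stochastic process (non-phase-locked bump,
    # ~10 Hz wide) riding on the broadband background; its band power during
    # stimulation rises by the contrast-dependent gain
    nb_sos = signal.butter(2, (truth.gamma_peak_freq - 5.0,
                               truth.gamma_peak_freq + 5.0),
                           btype="bandpass", fs=rate, output="sos")
    warmup = int(0.5 * rate)

    def draw_nb():
        white = rng.standard_normal(n_t + warmup)
        nb = signal.sosfilt(nb_sos, white)[warmup:]
        return nb / nb.std() / np.sqrt(2.0)

    if frozen_gamma:
        frozen = np.cos(2 * np.pi * truth.gamma_peak_freq * t
                        + rng.uniform(0, 2 * np.pi))
        frozen_bb = rng.normal(0.0, 1.0, n_t)

    def narrowband(amp):
        return amp * (frozen if frozen_gamma else draw_nb())

    data, conditions = [], []
    for _, block in schedule.entries.iterrows():
        cond = block["condition"]
        if cond == "rest":
            amp = a0
        else:
            amp = a0 * (1.0 + truth.gamma_pct(float(cond), schedule.eye)
                        / 100.0)
        for _ in range(trials_per_block):
            s = narrowband(amp)
            if bb_sd > 0:
                s = s + (bb_sd * frozen_bb if frozen_gamma
                         else rng.normal(0.0, bb_sd, n_t))
            if cond != "rest":
                s = s + evoked
            x = gain[:, None] * s[None, :]
            if sensor_sd > 0:
                x = x + rng.normal(0.0, sensor_sd, x.shape)
            data.append(x)
            conditions.append("rest" if cond == "rest" else f"{float(cond):g}")
    labels = pd.DataFrame({"condition": conditions,
                           "eye": schedule.eye})
    return SensorEpochs(np.array(data), rate, labels, array)


# ---------------------------------------------------------------------------
# Raw ASL simulation
# ---------------------------------------------------------------------------

DEFAULT_ASL_SHAPE = (12, 12, 6)
#: fraction of the echo-2 perfusion weighting relative to echo 1, and of the
#: echo-1 BOLD weighting relative to echo 2 (short vs long TE)
PERF_WEIGHT_ECHO2 = 0.5
BOLD_WEIGHT_ECHO1 = 0.2
TI2_S = 1.6
STATIC_E1, STATIC_E2 = 1000.0, 800.0
M0_BLOOD_DEFAULT = 1500.0


def default_active_roi(shape=DEFAULT_ASL_SHAPE) -> np.ndarray:
    """Ground-truth activated region: the central block of the grid."""
    mask = np.zeros(shape, bool)
    sl = tuple(slice(n // 2 - max(1, n // 6), n // 2 + max(1, n // 6))
               for n in shape)
    mask[sl] = True
    return mask


def slice_ti_offsets(n_slices: int, tr: float = TR_S) -> np.ndarray:
    """Per-slice TI increment for the ascending acquisition: k·TR/(2·n)."""
    return np.arange(n_slices) * tr / (2.0 * n_slices)


def _block_modulations(truth: SubjectTruth, schedule: BlockSchedule,
                       n_vols: int, tr: float):
    """HRF-convolved BOLD and CBF fractional modulations at volume times."""
    cond, _ = _condition_boxcars(schedule.entries, tr, n_vols)
    bold = np.zeros(n_vols)
    cbf = np.zeros(n_vols)
    for name, c in zip(cond, CONTRAST_LEVELS):
        bold += truth.bold_pct(c, schedule.eye) / 100.0 * cond[name]
        cbf += truth.cbf_pct(c, schedule.eye) / 100.0 * cond[name]
    return bold, cbf


def simulate_asl(truth: SubjectTruth, schedule: BlockSchedule, seed: int = 0,
                 shape=DEFAULT_ASL_SHAPE, tr: float = TR_S,
                 n_pairs: int = N_PAIRS,
                 params: aslkinetics.KineticParams | None = None
                 ) -> tuple[AslSeries, AslSeries]:
    """Dual-echo volume series for one eye's run (echo 1, echo 2).

    Echo 1 carries the static tissue signal plus the alternating ±half
    perfusion-weighted difference, whose amplitude follows the baseline CBF
    through the kinetic model and is block-modulated inside the active ROI;
    echo 2 carries the HRF-convolved BOLD response plus an attenuated
    alternating component.  A small BOLD leak is present on echo 1 (short
    but nonzero TE).
    """
    if tr <= 0 or n_pairs <= 0:
        raise ValueError("inconsistent grid/TR configuration")
    params = params or aslkinetics.KineticParams(m0_blood=M0_BLOOD_DEFAULT)
    rng = np.random.default_rng([int(seed), 202])
    n_vols = 2 * n_pairs
    parity = np.where(np.arange(n_vols) % 2 == 0, "tag", "control")
    sign = np.where(parity == "control", 1.0, -1.0)

    roi = default_active_roi(shape)
    nz = shape[2]
    ti2 = TI2_S + slice_ti_offsets(nz, tr)  # per-slice effective TI2
    p0_slice = aslkinetics.kinetic_model(
        ti2, truth.baseline_cbf, truth.arrival_time, params)
    p0 = np.broadcast_to(p0_slice, shape).copy()

    static1 = STATIC_E1 + rng.normal(0, 10.0, shape)
    static2 = STATIC_E2 + rng.normal(0, 10.0, shape)
    bold, cbf_mod = _block_modulations(truth, schedule, n_vols, tr)

    roi4 = roi[..., None].astype(float)
    p_t = p0[..., None] * (1.0 + roi4 * cbf_mod)          # (x,y,z,t)
    bold_t = roi4 * bold                                   # fractional

    sd = truth.noise["asl_sd"]
    e1 = (static1[..., None] * (1.0 + BOLD_WEIGHT_ECHO1 * bold_t)
          + sign * p_t / 2.0
          + rng.normal(0, sd, shape + (n_vols,)))
    e2 = (static2[..., None] * (1.0 + bold_t)
          + sign * PERF_WEIGHT_ECHO2 * p_t / 2.0
          + rng.normal(0, sd, shape + (n_vols,)))
    sched = schedule.entries
    return (AslSeries(e1, tr, 1, parity, sched),
            AslSeries(e2, tr, 2, parity, sched))


@dataclass
class MultiTiData:
    """Multi-TI mean tag-control differences on the acquisition grid."""

    dm: np.ndarray          # (x, y, z, n_ti) mean difference per TI
    ti: np.ndarray          # (n_ti,) nominal inversion times, s
    slice_offsets: np.ndarray  # (z,) per-slice TI increment, s
    repeats: int

    def roi_points(self, mask: np.ndarray):
        """Slice-resolved ROI samples for a joint kinetic fit.

        Averages the difference signal within the ROI per slice and pairs it
        with that slice's effective TI, so the per-slice acquisition-timing
        shift enters the fit instead of biasing an overall mean.  Returns
        flat ``(ti, dm)`` arrays.
        """
        mask = np.asarray(mask, bool)
        tis, dms = [], []
        for z in range(self.dm.shape[2]):
            sl = mask[:, :, z]
            if not sl.any():
                continue
            tis.append(self.ti + self.slice_offsets[z])
            dms.append(self.dm[:, :, z][sl].mean(axis=0))
        if not tis:
            raise ValueError("empty ROI")
        return np.concatenate(tis), np.concatenate(dms)


def simulate_multiti(truth: SubjectTruth, ti_list=None, repeats: int = 16,
                     seed: int = 0, shape=DEFAULT_ASL_SHAPE,
                     tr: float = TR_S,
                     params: aslkinetics.KineticParams | None = None
                     ) -> MultiTiData:
    """Multi-TI difference data from the kinetic model with truth CBF.

    Each voxel's mean difference at each (slice-adjusted) TI follows the
    QUIPSS II kinetic model at the subject's baseline CBF and arrival time,
    with Gaussian noise scaled by 1/sqrt(repeats).
    """
    if ti_list is None:
        ti_list = aslkinetics.DEFAULT_TI_GRID
    ti = np.asarray(ti_list, float)
    params = params or aslkinetics.KineticParams(m0_blood=M0_BLOOD_DEFAULT)
    rng = np.random.default_rng([int(seed), 303])
    offsets = slice_ti_offsets(shape[2], tr)
    dm = np.empty(shape + (len(ti),))
    for z in range(shape[2]):
        dm[:, :, z, :] = aslkinetics.kinetic_model(
            ti + offsets[z], truth.baseline_cbf, truth.arrival_time, params)
    plateau = 2 * params.m0_blood * params.inv_efficiency \
        * truth.baseline_cbf / aslkinetics.CBF_UNIT_FACTOR * params.ti1
    sd = truth.noise["multiti_sd_frac"] * plateau / np.sqrt(repeats)
    if sd > 0:
        dm = dm + rng.normal(0, sd, dm.shape)
    return MultiTiData(dm=dm, ti=ti, slice_offsets=offsets, repeats=repeats)


# ---------------------------------------------------------------------------
# Measurement-level cohort generator
# ---------------------------------------------------------------------------

def simulate_measurements(truths: list[SubjectTruth], seed: int = 0
                          ) -> pd.DataFrame:
    """Per-subject measured responses (truth + measurement noise).

    One row per subject × eye × contrast with measured peak gamma (%), BOLD
    (%), CBF (%) and quantified CBF (ml/100 g/min, derived from the measured
    CBF % and the measured baseline), plus the measured baseline CBF.  This
    is the observation model used for full-size group statistics; the raw
    signal chain is validated separately on small cohorts.
    """
    rng = np.random.default_rng([int(seed), 404])
    rows = []
    for truth in truths:
        nz = truth.noise
        baseline = truth.baseline_cbf + rng.normal(
            0, nz["meas_baseline_cbf_sd"])
        baseline = max(baseline, 5.0)
        for eye in EYES:
            for c in CONTRAST_LEVELS:
                gamma = truth.gamma_pct(c, eye) + rng.normal(
                    0, nz["meas_gamma_sd"])
                bold = truth.bold_pct(c, eye) + rng.normal(
                    0, nz["meas_bold_sd"])
                cbf = truth.cbf_pct(c, eye) + rng.normal(
                    0, nz["meas_cbf_sd"])
                rows.append({
                    "subject": truth.subject, "group": truth.group,
                    "eye": eye, "contrast": c,
                    "gamma_pct": gamma, "bold_pct": bold, "cbf_pct": cbf,
                    "cbf_quant": cbf / 100.0 * baseline,
                    "baseline_cbf": baseline,
                })
    return pd.DataFrame(rows)
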