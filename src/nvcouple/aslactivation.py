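"""Dual-echo ASL task analysis: BOLD and perfusion responses to the blocks.

The second echo is surround-averaged to cancel the tag/control alternation
and fitted with a conventional block GLM (BOLD percent signal change).  The
first echo is fitted directly with a GLM that models the alternation and its
interaction with each stimulus condition; the interaction betas, scaled by
the alternation beta (the baseline perfusion-weighted signal), give the
perfusion percent change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import AslSeries

CONDITION_NAMES = ("c6.25", "c12.5", "c25", "c50", "c100")
MEAN_CONTRAST = "mean"


def surround_average(series: AslSeries) -> np.ndarray:
    """Temporal (½, ¼, ¼) nearest-neighbor average along the volume axis.

    Cancels any purely alternating (tag/control) component exactly at
    interior volumes while passing constants and linear trends unchanged;
    endpoints use the mean with the single available neighbor.
    """
    x = np.asarray(series.volumes, float)
    t = x.shape[-1]
    if t < 3:
        raise ValueError("surround averaging needs at least 3 volumes")
    out = np.empty_like(x)
    out[..., 1:-1] = 0.5 * x[..., 1:-1] + 0.25 * (x[..., :-2] + x[..., 2:])
    out[..., 0] = 0.5 * (x[..., 0] + x[..., 1])
    out[..., -1] = 0.5 * (x[..., -1] + x[..., -2])
    return out


def _surround_1d(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    out[1:-1] = 0.5 * x[1:-1] + 0.25 * (x[:-2] + x[2:])
    out[0] = 0.5 * (x[0] + x[1])
    out[-1] = 0.5 * (x[-1] + x[-2])
    return out


def hrf_double_gamma(t, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1."""
    t = np.asarray(t, float)
    def g(t, shape):
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = np.exp((shape - 1) * np.log(t[pos]) - t[pos]
                          - gammaln(shape))
        return out
    h = g(t, peak) - ratio * g(t, undershoot)
    return h / h.max()


@dataclass
class DesignMatrix:
    """GLM design with named columns and condition contrasts.

    Columns: five HRF-convolved condition boxcars, the tag/control
    alternation (±½), five condition × alternation interactions, and
    Legendre drift terms (order 0 is the intercept).  ``contrasts`` maps the
    six contrast names (five conditions + cross-condition mean) to weight
    vectors over the condition (or interaction) columns.
    """

    matrix: pd.DataFrame
    contrasts: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def _condition_boxcars(schedule: pd.DataFrame, tr: float, n_vols: int,
                       dt: float = 0.1):
    """HRF-convolved condition regressors sampled at volume times, peak 1."""
    duration = n_vols * tr
    covered = (schedule["onset"] + schedule["duration"]).max()
    if duration > covered + tr:
        raise ValueError("schedule does not cover the scan duration")
    t_fine = np.arange(0, duration + 32.0, dt)
    hrf = hrf_double_gamma(np.arange(0, 32.0, dt))
    vol_t = np.arange(n_vols) * tr
    cols = {}
    for name, contrast in zip(
            CONDITION_NAMES, (0.0625, 0.125, 0.25, 0.5, 1.0)):
        box = np.zeros_like(t_fine)
        rows = schedule[np.isclose(
            schedule["condition"].astype(str).replace(
                "rest", "nan").astype(float), contrast)]
        for _, r in rows.iterrows():
            box[(t_fine >= r["onset"]) & (t_fine < r["onset"] + r["duration"])] = 1.0
        conv = np.convolve(box, hrf)[:len(t_fine)] * dt
        reg = np.interp(vol_t, t_fine, conv)
        peak = reg.max()
        cols[name] = reg / peak if peak > 0 else reg
    return cols, vol_t


def legendre_drift(n_vols: int, tr: float, cutoff_s: float = 90.0
                   ) -> np.ndarray:
    """Legendre drift columns, order 0..K with K = floor(2·T/cutoff)."""
    order = int(2 * n_vols * tr // cutoff_s)
    x = np.linspace(-1, 1, n_vols)
    return np.polynomial.legendre.legvander(x, order)


def build_design(schedule: pd.DataFrame, parity, tr: float, n_vols: int,
                 drift_cutoff_s: float = 90.0) -> DesignMatrix:
    """Design matrix for one eye's dual-echo run.

    The alternation column is +½ on control, −½ on tag volumes, so its beta
    equals the mean control-minus-tag (perfusion-weighted) signal.
    Interactions are the convolved condition regressors times the
    alternation, carrying the task modulation of perfusion.
    """
    parity = np.asarray(parity)
    if len(parity) != n_vols:
        raise ValueError("parity length must equal volume count")
    cond, _ = _condition_boxcars(schedule, tr, n_vols)
    alt = np.where(parity == "control", 0.5, -0.5)
    data = dict(cond)
    data["alternation"] = alt
    for name in CONDITION_NAMES:
        data[f"{name}:alt"] = cond[name] * alt
    drift = legendre_drift(n_vols, tr, drift_cutoff_s)
    for k in range(drift.shape[1]):
        data[f"drift{k}"] = drift[:, k]
    matrix = pd.DataFrame(data)
    contrasts = {name: _unit(matrix.columns, name) for name in CONDITION_NAMES}
    contrasts[MEAN_CONTRAST] = sum(
        contrasts[n] for n in CONDITION_NAMES) / len(CONDITION_NAMES)
    return DesignMatrix(matrix, contrasts)


def _unit(columns, name):
    w = np.zeros(len(columns))
    w[list(columns).index(name)] = 1.0
    return w


def _ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares betas for Y (t × voxels); raises on rank deficiency."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return beta


def glm_percent_change(series: AslSeries, design: DesignMatrix,
                       roi_mask: np.ndarray) -> pd.DataFrame:
    """ROI percent signal change per condition contrast for one echo.

    Echo 2 is surround-averaged and the condition betas are scaled by the
    intercept (drift-order-0) beta: BOLD percent change.  Echo 1 is fitted
    raw and the interaction betas are scaled by the alternation beta (the
    baseline perfusion-weighted signal): CBF percent change.  All condition
    regressors are peak-normalized, so a beta is directly the
    peak-to-baseline signal excursion.

    Returns a DataFrame with columns ``contrast`` (condition name) and
    ``pct_change``, ROI-averaged.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    X = design.values
    cols = list(design.matrix.columns)
    if series.echo == 2:
        data = surround_average(series)
        # the data were temporally filtered; filter the task model identically
        X = X.copy()
        for name in CONDITION_NAMES:
            X[:, cols.index(name)] = _surround_1d(X[:, cols.index(name)])
        Y = data[roi_mask].T  # t × voxels
        beta = _ols(X, Y)
        baseline = beta[cols.index("drift0")]
        task_cols = CONDITION_NAMES
    else:
        Y = series.volumes[roi_mask].T
        beta = _ols(X, Y)
        baseline = beta[cols.index("alternation")]
        task_cols = tuple(f"{n}:alt" for n in CONDITION_NAMES)
    if np.any(baseline == 0):
        raise ValueError("zero baseline signal in ROI")
    rows = []
    for name, col in zip(CONDITION_NAMES, task_cols):
        pct = 100.0 * beta[cols.index(col)] / baseline
        rows.append({"contrast": name, "pct_change": float(pct.mean())})
    rows.append({"contrast": MEAN_CONTRAST,
                 "pct_change": float(np.mean([r["pct_change"] for r in rows]))})
    return pd.DataFrame(rows)
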