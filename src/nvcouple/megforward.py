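"""Spherical-conductor MEG forward model and LCMV beamformer.

The forward model is the closed-form field of a current dipole inside a
homogeneous conducting sphere (Sarvas solution).  Two properties of that
solution matter downstream: a radially oriented dipole produces no external
magnetic field, and the *radial* field component equals the Biot–Savart field
of the primary dipole current alone (volume currents contribute only
tangentially).  Sensors here are point magnetometers oriented radially, so the
second property makes the whole pipeline independently checkable.

Source scanning follows the standard LCMV recipe: per-location lead fields
reduced to a single orientation by SVD, unit-gain minimum-variance weights
from a band-limited (30–80 Hz) covariance pooled over all trials, and a
stimulus-vs-rest percent-change power map searched inside an anatomical mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

MU0_OVER_4PI = 1e-7  # T·m/A

GAMMA_BAND = (30.0, 80.0)
#: reflective padding and edge trim used when band-filtering 1-s trials
FILTER_PAD_S = 0.2
EDGE_TRIM_S = 0.05


class DegenerateLeadfieldError(ValueError):
    """Raised when a lead field has no tangential (visible) component."""


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous spherical volume conductor."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.08  # m

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.radius <= 0:
            raise ValueError("head radius must be positive")


@dataclass(frozen=True)
class SensorArray:
    """Point-magnetometer array: positions and unit measurement orientations."""

    positions: np.ndarray   # (n, 3) m
    orientations: np.ndarray  # (n, 3), unit vectors

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def hemisphere_array(n_channels: int = 60, radius: float = 0.10,
                     center=(0.0, 0.0, 0.0)) -> SensorArray:
    """Deterministic Fibonacci-spiral array on the upper hemisphere.

    Sensors are radially oriented point magnetometers, a desk-scale stand-in
    for an axial-gradiometer helmet.
    """
    center = np.asarray(center, float)
    i = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    # z in (0, 1]: upper hemisphere only
    z = (i + 0.5) / n_channels
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z ** 2)
    units = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return SensorArray(positions=center + radius * units, orientations=units)


@dataclass
class SourceGrid:
    """Regular scanning grid with conductor-interior and anatomical masks."""

    locations: np.ndarray      # (n, 3) m
    spacing: float             # m
    inside_mask: np.ndarray    # (n,) bool — inside the conductor
    anatomical_mask: np.ndarray  # (n,) bool — peak-search region

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if np.any(self.anatomical_mask & ~self.inside_mask):
            raise ValueError("anatomical mask must lie inside the conductor")


def build_grid(head: HeadModel, spacing: float = 0.005,
               bounds=None, anat_center=None, anat_radius: float = 0.02,
               margin: float = 0.005) -> SourceGrid:
    """Regular grid over ``bounds`` (default: box around ``anat_center``).

    ``anat_center``/``anat_radius`` define a spherical stand-in for the
    calcarine/cuneus/lingual search region of a real anatomical mask.
    """
    if anat_center is None:
        anat_center = head.center + np.array([0.0, -0.05, 0.02])
    anat_center = np.asarray(anat_center, float)
    if bounds is None:
        half = anat_radius + 2 * spacing
        bounds = np.stack([anat_center - half, anat_center + half])
    axes = [np.arange(lo, hi + spacing / 2, spacing)
            for lo, hi in np.asarray(bounds, float).T]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts - head.center, axis=1)
    inside = r < head.radius - margin
    anat = inside & (np.linalg.norm(pts - anat_center, axis=1) <= anat_radius)
    return SourceGrid(pts, spacing, inside, anat)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def sphere_leadfield(source_loc, sensors: SensorArray, head: HeadModel
                     ) -> np.ndarray:
    """Lead field of unit dipoles along x, y, z at ``source_loc``.

    Returns an (n_channels, 3) matrix in T per A·m: column j is the sensor
    reading produced by a unit dipole along axis j, using the closed-form
    current-dipole-in-sphere field projected on each sensor's orientation.
    The purely radial dipole component lies in this matrix's null space.
    """
    r0 = np.asarray(source_loc, float) - head.center
    if np.linalg.norm(r0) >= head.radius:
        raise ValueError("source must lie strictly inside the conductor")
    r = sensors.positions - head.center  # (n, 3)
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= head.radius):
        raise ValueError("sensors must lie strictly outside the conductor")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    r0_dot_r = r @ r0
    F = a * (rn * a + rn ** 2 - r0_dot_r)
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    c1 = a ** 2 / rn + a_dot_r / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + a_dot_r / a
    gradF = c1[:, None] * r - c2[:, None] * r0[None, :]

    L = np.empty((sensors.n_channels, 3))
    for j, q in enumerate(np.eye(3)):
        qxr0 = np.cross(q, r0)
        B = (F[:, None] * qxr0[None, :]
             - (r @ qxr0)[:, None] * gradF) * (MU0_OVER_4PI / F ** 2)[:, None]
        L[:, j] = np.einsum("ij,ij->i", B, sensors.orientations)
    return L


def dipole_field(source_loc, moment, sensors: SensorArray, head: HeadModel
                 ) -> np.ndarray:
    """Sensor readings of a dipole with the given moment (A·m)."""
    return sphere_leadfield(source_loc, sensors, head) @ np.asarray(moment, float)


def reduce_orientation(L3: np.ndarray, atol: float = 0.0):
    """Collapse a 3-column lead field to its dominant single orientation.

    Returns ``(l, v)`` where ``v`` is the right singular vector of the largest
    singular value (the SVD-optimal dipole orientation) and ``l = L3 @ v``.
    The sign is fixed so the largest-magnitude element of ``l`` is positive.
    """
    L3 = np.asarray(L3, float)
    u, s, vt = np.linalg.svd(L3, full_matrices=False)
    if s[0] <= atol or not np.isfinite(s[0]):
        raise DegenerateLeadfieldError(
            "lead field is (numerically) zero: radial-only source")
    v = vt[0]
    l = L3 @ v
    if l[np.argmax(np.abs(l))] < 0:
        l, v = -l, -v
    return l, v


# ---------------------------------------------------------------------------
# Beamformer
# ---------------------------------------------------------------------------

def lcmv_weights(L: np.ndarray, C: np.ndarray, lambda_reg: float = 0.05
                 ) -> np.ndarray:
    """Unit-gain minimum-variance spatial filter.

    ``w = C_r^-1 L / (L' C_r^-1 L)`` with ``C_r = C + lambda_reg·mean(diag C)·I``.
    """
    L = np.asarray(L, float)
    C = np.asarray(C, float)
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance must be symmetric")
    Cr = C + lambda_reg * np.mean(np.diag(C)) * np.eye(C.shape[0])
    try:
        CiL = linalg.solve(Cr, L, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "regularized covariance is singular; increase lambda_reg") from err
    denom = L @ CiL
    if denom <= 0 or not np.isfinite(denom):
        raise linalg.LinAlgError(
            "covariance is rank deficient at this location; "
            "increase lambda_reg")
    return CiL / denom


def bandpass_sos(rate: float, band=GAMMA_BAND, order: int = 4):
    return signal.butter(order, band, btype="bandpass", fs=rate, output="sos")


def _filter_trials(data: np.ndarray, rate: float, band=GAMMA_BAND,
                   order: int = 4) -> np.ndarray:
    """Zero-phase band-pass with reflective padding, per trial.

    ``data``: (trials, channels, time). Padding avoids filter transients at
    the 1-s trial edges; the pad is stripped before returning.
    """
    pad = int(round(FILTER_PAD_S * rate))
    sos = bandpass_sos(rate, band, order)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)],
                    mode="reflect")
    out = signal.sosfiltfilt(sos, padded, axis=-1)
    return out[..., pad:-pad]


def band_covariance(data: np.ndarray, rate: float, band=GAMMA_BAND
                    ) -> np.ndarray:
    """Sensor covariance after band-pass filtering, pooled over trials.

    The first/last 50 ms of each filtered trial are excluded.
    """
    filt = _filter_trials(np.asarray(data, float), rate, band)
    trim = int(round(EDGE_TRIM_S * rate))
    filt = filt[..., trim:-trim]
    x = np.moveaxis(filt, 1, 0).reshape(filt.shape[1], -1)
    x = x - x.mean(axis=1, keepdims=True)
    return x @ x.T / x.shape[1]


def scan_percent_change(epochs, grid: SourceGrid, head: HeadModel,
                        lambda_reg: float = 0.05, band=GAMMA_BAND):
    """Whole-grid stimulus-vs-rest gamma power change and its masked peak.

    For each in-conductor grid location the LCMV output power is computed for
    the stimulus-trial and rest-trial band-limited covariances, using weights
    from the covariance pooled over *all* trials, and expressed as
    ``100·(P_stim − P_rest)/P_rest``.  The peak is the arg-max restricted to
    the anatomical mask; exact ties resolve to the lowest linear index.

    Returns ``(pct_map, peak_index, peak_weights)``; locations outside the
    conductor are NaN in the map.
    """
    stim = epochs.data[epochs.is_stimulus]
    rest = epochs.data[~epochs.is_stimulus]
    if len(stim) == 0 or len(rest) == 0:
        raise ValueError("need both stimulus and rest trials")
    if not grid.anatomical_mask.any():
        raise ValueError("empty anatomical mask")
    rate = epochs.rate
    C_all = band_covariance(epochs.data, rate, band)
    C_stim = band_covariance(stim, rate, band)
    C_rest = band_covariance(rest, rate, band)

    sensors = epochs.sensors
    pct = np.full(len(grid.locations), np.nan)
    weights = {}
    for i in np.flatnonzero(grid.inside_mask):
        L3 = sphere_leadfield(grid.locations[i], sensors, head)
        try:
            l, _ = reduce_orientation(L3, atol=1e-25)
        except DegenerateLeadfieldError:
            continue
        w = lcmv_weights(l, C_all, lambda_reg)
        p_stim = w @ C_stim @ w
        p_rest = w @ C_rest @ w
        pct[i] = 100.0 * (p_stim - p_rest) / p_rest
        if grid.anatomical_mask[i]:
            weights[i] = w
    masked = np.where(grid.anatomical_mask, pct, -np.inf)
    masked[~np.isfinite(masked)] = -np.inf
    peak = int(np.argmax(masked))  # argmax takes the lowest index on ties
    return pct, peak, weights[peak]


def virtual_sensor(epochs, w: np.ndarray) -> np.ndarray:
    """Project sensor epochs through beamformer weights.

    Returns a (trials, time) source-level series at the input sampling rate.
    """
    w = np.asarray(w, float)
    if epochs.data.shape[1] != w.shape[0]:
        raise ValueError("weight vector does not match channel count")
    return np.einsum("c,tcs->ts", w, epochs.data)
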