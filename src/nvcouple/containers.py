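"""In-memory containers and on-disk formats.

SensorEpochs round-trips through an HDF5 container (datasets: ``data``
[trial × channel × time], per-trial labels, sampling rate, sensor geometry).
AslSeries round-trips through NIfTI (one file per echo) plus a JSON sidecar
carrying TR, tag/control parity and the block schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .megforward import SensorArray

REST = "rest"


@dataclass
class SensorEpochs:
    """channels × time MEG trials with condition labels and geometry.

    ``labels`` has one row per trial with columns ``condition`` (the contrast
    fraction as a string, or ``"rest"``) and ``eye``.
    """

    data: np.ndarray          # (trials, channels, time)
    rate: float               # Hz
    labels: pd.DataFrame
    sensors: SensorArray

    def __post_init__(self):
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/trials mismatch")

    @property
    def is_stimulus(self) -> np.ndarray:
        return (self.labels["condition"] != REST).to_numpy()

    @property
    def contrasts(self) -> np.ndarray:
        """Sorted unique stimulus contrast fractions present."""
        vals = self.labels.loc[self.is_stimulus, "condition"].astype(float)
        return np.array(sorted(vals.unique()))

    def select(self, condition=None) -> "SensorEpochs":
        """Subset trials by condition label (contrast fraction or 'rest')."""
        key = REST if condition == REST else f"{float(condition):g}"
        mask = (self.labels["condition"] == key).to_numpy()
        return SensorEpochs(self.data[mask], self.rate,
                            self.labels[mask].reset_index(drop=True),
                            self.sensors)

    def to_hdf5(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["rate"] = self.rate
            lab = f.create_group("labels")
            lab.create_dataset(
                "condition",
                data=self.labels["condition"].astype("S").to_numpy())
            lab.create_dataset(
                "eye", data=self.labels["eye"].astype("S").to_numpy())
            geo = f.create_group("sensors")
            geo.create_dataset("positions", data=self.sensors.positions)
            geo.create_dataset("orientations", data=self.sensors.orientations)

    @classmethod
    def from_hdf5(cls, path) -> "SensorEpochs":
        with h5py.File(path, "r") as f:
            labels = pd.DataFrame({
                "condition": [s.decode() for s in f["labels/condition"][...]],
                "eye": [s.decode() for s in f["labels/eye"][...]],
            })
            return cls(
                data=f["data"][...],
                rate=float(f.attrs["rate"]),
                labels=labels,
                sensors=SensorArray(f["sensors/positions"][...],
                                    f["sensors/orientations"][...]),
            )


@dataclass
class AslSeries:
    """4D echo-specific ASL volume series with tag/control parity."""

    volumes: np.ndarray       # (x, y, z, t)
    tr: float                 # s
    echo: int                 # 1 (perfusion-weighted) or 2 (BOLD-weighted)
    parity: np.ndarray        # (t,) strings "tag"/"control", strictly alternating
    schedule: pd.DataFrame    # columns condition, onset, duration

    def __post_init__(self):
        t = self.volumes.shape[-1]
        self.parity = np.asarray(self.parity)
        if len(self.parity) != t:
            raise ValueError("parity length must equal number of volumes")
        if t % 2:
            raise ValueError("volume count must be even (tag/control pairs)")
        vals = np.unique(self.parity)
        if not set(vals) <= {"tag", "control"}:
            raise ValueError("parity labels must be 'tag'/'control'")
        if np.any(self.parity[1:] == self.parity[:-1]):
            raise ValueError("tag/control parity must alternate strictly")
        if self.echo not in (1, 2):
            raise ValueError("echo must be 1 or 2")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[-1] // 2

    @property
    def parity_sign(self) -> np.ndarray:
        """+1 for control volumes, -1 for tag volumes."""
        return np.where(self.parity == "control", 1.0, -1.0)

    def times(self) -> np.ndarray:
        return np.arange(self.volumes.shape[-1]) * self.tr

    def to_nifti(self, path, sidecar_path=None):
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.volumes.astype(np.float32), affine), path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as f:
                json.dump({
                    "tr": self.tr,
                    "echo": self.echo,
                    "parity": self.parity.tolist(),
                    "schedule": self.schedule.to_dict(orient="list"),
                }, f)

    @classmethod
    def from_nifti(cls, path, sidecar_path) -> "AslSeries":
        img = nib.load(path)
        with open(sidecar_path) as f:
            meta = json.load(f)
        return cls(
            volumes=np.asarray(img.dataobj, dtype=float),
            tr=float(meta["tr"]),
            echo=int(meta["echo"]),
            parity=np.array(meta["parity"]),
            schedule=pd.DataFrame(meta["schedule"]),
        )


def save_map_nifti(values: np.ndarray, path, affine=None):
    """Write a 3D (or 4D) map as NIfTI with an identity affine by default."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(values, np.float32), affine), path)


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")
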