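#!/usr/bin/env python
"""Simulate a small raw-data cohort and write it to disk.

Generates MEG sensor epochs (HDF5), dual-echo ASL series (NIfTI + JSON
sidecar), multi-TI baseline data and the ground-truth parameters (JSON) for
four subjects (two controls, two patients), at reduced trial counts and
volume grids so the whole raw chain stays desk-scale.  Downstream scripts
read these files back, so the on-disk formats are exercised end to end.
"""

import json
from pathlib import Path

import numpy as np

from nvcouple import synthdata as sd
from nvcouple.containers import write_json

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
TRIALS_PER_BLOCK = 2
ASL_SHAPE = (8, 8, 4)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    truths = [sd.sample_subject("control", f"ctl{i}", rng) for i in range(2)]
    truths += [sd.sample_subject("patient", f"pat{i}", rng) for i in range(2)]

    manifest = []
    for i, truth in enumerate(truths):
        subj_dir = OUT / truth.subject
        subj_dir.mkdir(exist_ok=True)
        for k, eye in enumerate(sd.EYES):
            schedule = sd.make_schedule(SEED + i, eye)
            epochs = sd.simulate_meg(truth, schedule, seed=SEED + 10 * i + k,
                                     trials_per_block=TRIALS_PER_BLOCK)
            epochs.to_hdf5(subj_dir / f"meg_{eye}.h5")
            e1, e2 = sd.simulate_asl(truth, schedule,
                                     seed=SEED + 10 * i + k + 5,
                                     shape=ASL_SHAPE)
            for echo, series in ((1, e1), (2, e2)):
                series.to_nifti(subj_dir / f"asl_{eye}_echo{echo}.nii.gz",
                                subj_dir / f"asl_{eye}_echo{echo}.json")
        multiti = sd.simulate_multiti(truth, seed=SEED + 10 * i + 3,
                                      shape=ASL_SHAPE)
        np.save(subj_dir / "multiti_dm.npy", multiti.dm)
        write_json({"ti": multiti.ti, "slice_offsets": multiti.slice_offsets,
                    "repeats": multiti.repeats}, subj_dir / "multiti.json")
        write_json({
            "subject": truth.subject, "group": truth.group,
            "gamma_peak_freq": truth.gamma_peak_freq,
            "evoked_latency_ms": truth.evoked_latency_ms,
            "bold_slope": truth.bold_slope, "cbf_slope": truth.cbf_slope,
            "baseline_cbf": truth.baseline_cbf,
            "arrival_time": truth.arrival_time,
            "gamma_pct_c100": truth.gamma_pct(1.0),
        }, subj_dir / "truth.json")
        manifest.append({"subject": truth.subject, "group": truth.group})
        print(f"wrote {truth.subject} ({truth.group})")

    (OUT / "manifest.json").write_text(json.dumps(
        {"seed": SEED, "trials_per_block": TRIALS_PER_BLOCK,
         "asl_shape": list(ASL_SHAPE), "subjects": manifest}, indent=2))
    print(f"cohort written to {OUT}")


if __name__ == "__main__":
    main()
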