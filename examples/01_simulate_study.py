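"""Simulate a small synthetic study and inspect the generator.

Walks through the generator layer by layer: sensor layout, canonical
topographies, semi-Markov state dynamics, and voltage synthesis, then
materializes a scaled-down study as EDF files.

Run:  python examples/01_simulate_study.py
"""

import tempfile
from pathlib import Path

import numpy as np

import microband as mb
from microband.edf import read_edf, write_edf

# sensor layout and canonical topographies --------------------------------
layout = mb.make_layout(31)
templates = mb.make_canonical_templates(layout)
cos = templates.maps @ templates.maps.T
print("canonical templates:", templates.labels)
print("max |cos| between distinct templates:",
      round(float(np.abs(cos[~np.eye(4, dtype=bool)]).max()), 3))

# semi-Markov dynamics -----------------------------------------------------
spec = mb.DynamicsSpec(mean_duration_ms=np.array([120.0, 100.0, 90.0, 80.0]),
                       snr=5.0)
labels = mb.sample_state_sequence(spec, duration_s=7.0, fs=250.0, rng_seed=0)
runs = np.diff(np.concatenate(
    [[0], np.flatnonzero(np.diff(labels)) + 1, [labels.size]]))
print(f"\none 7 s epoch: {runs.size} dwells, "
      f"mean {runs.mean() * 4:.0f} ms at 250 Hz")

# voltage synthesis --------------------------------------------------------
v = mb.synthesize_epoch(labels, templates, spec, fs=250.0, rng_seed=1)
print("epoch shape (channels x samples):", v.shape)
print("peak |voltage| (uV):", round(float(np.abs(v).max()), 1))

# a scaled-down study written as EDF ---------------------------------------
design = mb.StudyDesign(n_per_group=2, trials_per_condition=3,
                        resting_duration_s=22.0, n_channels=16,
                        fs_hz=250.0)
study = mb.synthesize_study(design, spec, seed=7)
out = Path(tempfile.mkdtemp(prefix="microband_study_"))
for rec in study.iter_recordings():
    write_edf(rec, out / f"{rec.subject}_{rec.condition}.edf")
print(f"\nwrote {study.n_recordings} EDF recordings to {out}")

back = read_edf(out / "MUD01_resting.edf")
print("round-trip check: fs", back.fs, "channels", back.n_channels)
print("\nsubject table:")
print(study.subjects.head())
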