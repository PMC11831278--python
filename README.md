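# microband

Band-resolved EEG microstate analysis with a built-in synthetic study
generator.  The package emulates a two-group (methamphetamine use
disorder vs. healthy control) EEG study end to end: it simulates
multichannel EEG with planted microstate dynamics, preprocesses it into
band-limited epochs, fits a polarity-invariant microstate model, derives
the standard per-epoch microstate parameters, classifies the groups per
frequency band and condition with random forests, and checks the age
covariate with per-parameter ANCOVAs.

Because the study it emulates did not deposit its recordings, nothing
here reproduces real-data numbers.  What the package does reproduce
exactly is the study's *design bookkeeping* (subjects, trials, epochs,
bands, features), and every analytic step is validated by property-based
tests against planted ground truth.

## What is in the box

| Module | Contents |
| --- | --- |
| `microband.synthetic` | sensor layouts, canonical A–D topographies, semi-Markov state dynamics, voltage synthesis, full-study simulation, and a fast dynamics-level feature generator |
| `microband.preprocess` | zero-phase FIR band-pass filters, anti-aliased downsampling, trial epoching, sub-band splitting |
| `microband.microstate` | GFP and GFP-peak extraction, polarity-invariant modified k-means (with an exhaustive-assignment oracle for small instances), canonical labeling, back-fitting, the 17 per-epoch parameters |
| `microband.classify` | outlier filtering, leak-free fold-wise z-scoring, 5-fold random-forest classification (trial- or subject-wise splits), Breiman out-of-bag permutation importance |
| `microband.covariates` | trial averaging and per-parameter `parameter ~ Group * Age` ANCOVAs (Type-II tests) |
| `microband.edf`, `microband.cli`, `microband.pipeline`, `microband.config` | EDF I/O, a thin `microband` CLI, the orchestrated `run_all`, and a validated YAML configuration |

## Quick start

```python
import microband as mb

# one 7 s epoch of synthetic 31-channel EEG with planted dynamics
layout = mb.make_layout(31)
templates = mb.make_canonical_templates(layout)
spec = mb.DynamicsSpec(snr=5.0)
labels = mb.sample_state_sequence(spec, duration_s=7.0, fs=250.0, rng_seed=0)
v = mb.synthesize_epoch(labels, templates, spec, fs=250.0, rng_seed=1)
```

The full pipeline runs from one validated configuration:

```python
from microband.config import PipelineConfig
from microband.pipeline import run_all

result = run_all(PipelineConfig(seed=1, n_trees=100))
print(result.manifest["counts"])
```

prints, with the default design (2 × 20 subjects, 3 conditions,
15 × 7 s trials, 5 bands):

```
{'recordings': 120, 'all_band_epochs': 1800, 'pooled_peak_maps': 40000,
 'training_gev': 0.794, 'sub_band_epochs': 7200, 'feature_epochs': 9000,
 'features_per_epoch': 17, 'outlier_filter': {...}}
```

Shell use:

```
microband simulate --out study/ --seed 1      # EDF files + design.csv + ground_truth.json
microband run-all  --out run/   --seed 1      # every stage output as CSV/JSON
```

The `examples/` directory contains four narrative scripts covering the
generator, the microstate core, the classification grid, and the
ANCOVA; each runs standalone in well under a minute.

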