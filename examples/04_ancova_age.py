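"""Age-covariate ANCOVA on trial-averaged subject-level parameters.

The two groups differ in mean age by design, so any group difference in
a microstate parameter could in principle be an age artifact.  The
ANCOVA fits ``parameter ~ Group + Age + Group x Age`` per parameter and
reports Type-II F tests for the Age main effect and the interaction.

Run:  python examples/04_ancova_age.py
"""

import numpy as np

import microband as mb
from microband.classify import filter_outliers
from microband.covariates import ancova_age, ancova_table, average_trials

design = mb.StudyDesign(n_per_group=17)  # the emulated study's group sizes
table = mb.simulate_feature_table(design, mb.DynamicsSpec(), seed=5,
                                  bands=("alpha",))
cell = table[(table.band == "alpha") & (table.condition == "resting")]
cell, log = filter_outliers(cell.reset_index(drop=True))
print("outlier filter:", log)

subjects = average_trials(cell)
print(f"{len(subjects)} subject-level rows "
      f"(ages {subjects.age.min():.0f}-{subjects.age.max():.0f})")

# full 17-parameter x 2-term table -----------------------------------------
out = ancova_table(subjects)
print("\nsmallest Age p-values (null study -> should be unremarkable):")
print(out[out.term == "Age"].nsmallest(3, "p")
      [["parameter", "F", "p"]].round(4).to_string(index=False))

# plant an age slope and watch the ANCOVA find it ---------------------------
planted = subjects.copy()
planted["duration_A"] = planted["duration_A"] + 0.5 * planted["age"]
res = ancova_age(planted, "duration_A")
print("\nplanted 0.5 ms/year slope on duration_A:")
print(res.round(5).to_string(index=False))
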