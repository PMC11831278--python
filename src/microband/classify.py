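"""Feature filtering, normalization, random-forest classification, and
out-of-bag permutation importance.

The feature table carries the 17 per-epoch microstate parameters
(coverage, duration, occurrence, GEV per class A-D, plus total GEV).
Group classification is run per band x condition cell with 5-fold
cross-validation; the default fold scheme is trial-random (stratified),
with a subject-wise grouped scheme as a first-class alternative that
prevents a subject's trials from straddling the train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from microband.synthetic import CLASS_NAMES

#: The 17 feature columns, in canonical order.
FEATURE_COLUMNS: list[str] = (
    [f"coverage_{c}" for c in CLASS_NAMES]
    + [f"duration_{c}" for c in CLASS_NAMES]
    + [f"occurrence_{c}" for c in CLASS_NAMES]
    + [f"gev_{c}" for c in CLASS_NAMES]
    + ["gev_total"]
)

DURATION_COLUMNS = [f"duration_{c}" for c in CLASS_NAMES]


# ---------------------------------------------------------------------------
# outlier filtering and normalization
# ---------------------------------------------------------------------------

def filter_outliers(
    table: pd.DataFrame,
    max_duration_ms: float = 250.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop epochs with degenerate microstate durations.

    An epoch is removed when any class duration is zero (the class never
    appears) or exceeds ``max_duration_ms`` (default 250 ms, far above
    the typical 60-100 ms microstate dwell).  Returns the retained rows
    and a per-reason removal log.
    """
    dur = table[DURATION_COLUMNS]
    zero = (dur == 0).any(axis=1)
    long = (dur > max_duration_ms).any(axis=1)
    keep = ~(zero | long)
    log = {
        "duration_zero": int(zero.sum()),
        "duration_over_max": int(long.sum()),
        "removed": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    return table.loc[keep].reset_index(drop=True), log


def normalize_features(
    train: pd.DataFrame,
    apply: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature z-scoring with training-fold statistics only.

    Uses the population standard deviation (divisor n).  A constant
    training feature is passed through centered (all zeros) with a
    warning.  The identical transform is applied to the held-out rows,
    so no test-set statistic ever leaks into the scaling.
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    mean = train[feature_cols].mean()
    sd = train[feature_cols].std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"constant training features centered only: {degenerate}",
                      stacklevel=2)
    sd = sd.replace(0.0, 1.0)
    out = []
    for df in (train, apply):
        z = df.copy()
        z[feature_cols] = (df[feature_cols] - mean) / sd
        out.append(z)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cross-validated random forest
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Fold accuracies for one band x condition (or contrast) cell."""

    band: str
    condition: str
    contrast: str
    fold_accuracies: list[float]
    n_rows: int
    cv_mode: str
    seed: int
    group: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def as_row(self) -> dict:
        row = {"band": self.band, "condition": self.condition,
               "contrast": self.contrast, "group": self.group,
               "mean_accuracy": self.mean_accuracy,
               "sd_accuracy": self.sd_accuracy, "n_rows": self.n_rows,
               "cv_mode": self.cv_mode, "seed": self.seed}
        for i, acc in enumerate(self.fold_accuracies):
            row[f"acc_fold{i + 1}"] = acc
        return row


def _check_classes(y: pd.Series) -> None:
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("classification needs at least 2 classes")
    if counts.min() < 10:
        raise ValueError("need at least 10 rows per class")


def crossval_rf(
    table: pd.DataFrame,
    label_col: str = "group",
    cv_mode: str = "trial",
    n_trees: int = 500,
    n_splits: int = 5,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    band: str = "",
    condition: str = "",
    contrast: str = "",
    group: str = "",
) -> ClassificationReport:
    """5-fold random-forest classification of one feature table.

    ``cv_mode='trial'`` uses stratified shuffled folds over epochs (the
    study-faithful default, which lets one subject's trials land on both
    sides of the split); ``cv_mode='subject'`` uses grouped folds so no
    subject straddles the split.  Features are z-scored with
    training-fold statistics inside each fold.
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    y = table[label_col].astype(str)
    _check_classes(y)
    if cv_mode == "trial":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(table, y)
    elif cv_mode == "subject":
        splitter = GroupKFold(n_splits=n_splits)
        splits = splitter.split(table, y, groups=table["subject"])
    else:
        raise ValueError(f"unknown cv_mode {cv_mode!r}")

    accs = []
    for fold, (tr, te) in enumerate(splits):
        tr_df, te_df = table.iloc[tr], table.iloc[te]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr_z, te_z = normalize_features(tr_df, te_df, feature_cols)
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=seed * 1000 + fold, n_jobs=1)
        clf.fit(tr_z[feature_cols].to_numpy(), y.iloc[tr])
        pred = clf.predict(te_z[feature_cols].to_numpy())
        accs.append(float(np.mean(pred == y.iloc[te].to_numpy())))
    return ClassificationReport(
        band=band, condition=condition, contrast=contrast, group=group,
        fold_accuracies=accs, n_rows=len(table), cv_mode=cv_mode, seed=seed)


# ---------------------------------------------------------------------------
# out-of-bag permutation importance
# ---------------------------------------------------------------------------

def _feature_identity(name: str) -> tuple[str, str]:
    if name == "gev_total":
        return "Total", "GEV"
    param, cls = name.split("_")
    pretty = {"coverage": "Coverage", "duration": "Duration",
              "occurrence": "Occurrence", "gev": "GEV"}[param]
    return cls, pretty


def oob_importance(
    table: pd.DataFrame,
    label_col: str = "group",
    n_trees: int = 500,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Breiman out-of-bag permutation importance of the 17 features.

    A bagged ensemble of decision trees is grown on bootstrap samples
    (sqrt-p features per split); for every tree the accuracy on its
    out-of-bag rows is compared with the accuracy after permuting one
    feature among those rows, and the drop is averaged over trees.
    Returns the full descending ranking with the class/parameter
    identity of each feature.
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    y = table[label_col].astype(str)
    _check_classes(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z, _ = normalize_features(table, table, feature_cols)
    x = z[feature_cols].to_numpy()
    yv = y.to_numpy()
    n, p = x.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(2 ** 31 - 1)))
        tree.fit(x[boot], yv[boot])
        base = np.mean(tree.predict(x[oob]) == yv[oob])
        x_oob = x[oob]
        for f in range(p):
            perm = x_oob.copy()
            perm[:, f] = perm[rng.permutation(oob.size), f]
            drops[f] += base - np.mean(tree.predict(perm) == yv[oob])
        used += 1
    drops /= max(used, 1)
    rows = []
    for name, imp in zip(feature_cols, drops):
        cls, param = _feature_identity(name)
        rows.append({"microstate": cls, "parameter": param,
                     "feature": name, "importance": float(imp)})
    out = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def impurity_importance(
    table: pd.DataFrame,
    label_col: str = "group",
    n_trees: int = 500,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Gini impurity-decrease importance (cross-check for the OOB rank)."""
    feature_cols = feature_cols or FEATURE_COLUMNS
    y = table[label_col].astype(str)
    _check_classes(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z, _ = normalize_features(table, table, feature_cols)
    clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed, n_jobs=1)
    clf.fit(z[feature_cols].to_numpy(), y)
    rows = []
    for name, imp in zip(feature_cols, clf.feature_importances_):
        cls, param = _feature_identity(name)
        rows.append({"microstate": cls, "parameter": param,
                     "feature": name, "importance": float(imp)})
    return pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="mergesort").reset_index(drop=True)


def oob_exclusion_fraction(n: int = 1000, reps: int = 1000,
                           seed: int = 0) -> float:
    """Mean fraction of distinct rows an n-row bootstrap leaves out.

    Converges to ``(1 - 1/n)^n -> e^-1 ~ 0.368`` — the share of data each
    tree can use as an internal validation set.
    """
    rng = np.random.default_rng(seed)
    fracs = np.empty(reps)
    for r in range(reps):
        boot = rng.integers(0, n, n)
        fracs[r] = 1.0 - np.unique(boot).size / n
    return float(fracs.mean())


# ---------------------------------------------------------------------------
# the full band x condition grid
# ---------------------------------------------------------------------------

def run_grid(
    table: pd.DataFrame,
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma", "all"),
    conditions: tuple[str, ...] = ("resting", "drug", "neutral"),
    cue_conditions: tuple[str, ...] = ("drug", "neutral"),
    cv_mode: str = "trial",
    n_trees: int = 500,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Group classification per band x condition plus rest-vs-task cells.

    Produces the 5 x 3 = 15 group-classification reports and, per group
    and cue type, the 2 x 2 x 5 = 20 rest-vs-task reports.  Cells that
    cannot be classified (missing rows or a single class) are listed as
    skipped rather than aborting the grid.
    """
    rows = []
    for band in bands:
        for cond in conditions:
            cell = table[(table.band == band) & (table.condition == cond)]
            row_meta = {"band": band, "condition": cond,
                        "contrast": "group", "group": ""}
            try:
                rep = crossval_rf(cell.reset_index(drop=True),
                                  label_col="group", cv_mode=cv_mode,
                                  n_trees=n_trees, seed=seed,
                                  feature_cols=feature_cols, band=band,
                                  condition=cond, contrast="group")
                rows.append(rep.as_row())
            except ValueError as exc:
                rows.append({**row_meta, "skipped": str(exc)})
    for grp in sorted(table.group.unique()):
        for cue in cue_conditions:
            for band in bands:
                cell = table[(table.band == band) & (table.group == grp)
                             & (table.condition.isin(["resting", cue]))]
                cell = cell.reset_index(drop=True).copy()
                cell["is_resting"] = np.where(
                    cell.condition == "resting", "rest", "task")
                contrast = f"rest-vs-{cue}"
                meta = {"band": band, "condition": "",
                        "contrast": contrast, "group": grp}
                try:
                    rep = crossval_rf(cell, label_col="is_resting",
                                      cv_mode=cv_mode, n_trees=n_trees,
                                      seed=seed, feature_cols=feature_cols,
                                      band=band, contrast=contrast,
                                      group=grp)
                    rows.append(rep.as_row())
                except ValueError as exc:
                    rows.append({**meta, "skipped": str(exc)})
    return pd.DataFrame(rows)
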