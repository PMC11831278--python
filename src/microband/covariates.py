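"""Subject-level averaging and the ANCOVA age-covariate check.

The two groups in the emulated study differ in mean age, so before
interpreting any group difference in microstate statistics the age
covariate must be shown not to drive them: per parameter, the linear
model ``parameter ~ Group + Age + Group x Age`` is fitted on
trial-averaged subject-level values and Type-II F tests are reported for
the Age main effect and the Group x Age interaction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from microband.classify import FEATURE_COLUMNS


def average_trials(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Average surviving trials into one row per subject x band x condition.

    Assumes outlier filtering has already been applied; subjects whose
    every trial in a cell was filtered out simply have no row in that
    cell (a warning names them when a design column is present).
    """
    feature_cols = feature_cols or FEATURE_COLUMNS
    keys = [c for c in ("subject", "group", "condition", "band", "age")
            if c in table.columns]
    grouped = (table.groupby(keys, as_index=False, sort=True)[feature_cols]
               .mean())
    return grouped


def _check_design(sub_table: pd.DataFrame) -> None:
    if sub_table["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    if np.var(sub_table["age"].to_numpy()) == 0:
        raise ValueError("singular design: 'age' has zero variance "
                         "(collinear with the intercept)")


def ancova_age(sub_table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """ANCOVA of one microstate parameter with age as covariate.

    Fits ``parameter ~ C(group) * age`` by OLS on the subject-level
    table and returns Type-II sums of squares, df, F and p for the Age
    main effect and the Group x Age interaction.
    """
    _check_design(sub_table)
    df = sub_table.rename(columns={parameter: "_y"})
    model = smf.ols("_y ~ C(group) * age", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    out_rows = []
    for term, label in (("age", "Age"), ("C(group):age", "Age x Group")):
        row = table.loc[term]
        out_rows.append({
            "parameter": parameter,
            "term": label,
            "sum_sq": float(row["sum_sq"]),
            "df": int(row["df"]),
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
        })
    return pd.DataFrame(out_rows)


def ancova_table(
    sub_table: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """The full 17-parameter x 2-term ANCOVA table for one cell."""
    feature_cols = feature_cols or FEATURE_COLUMNS
    return pd.concat([ancova_age(sub_table, p) for p in feature_cols],
                     ignore_index=True)


def type1_age_ss(sub_table: pd.DataFrame, parameter: str) -> float:
    """Type-I (sequential) sum of squares for Age, as a cross-check.

    With balanced groups and an age covariate orthogonalized against
    group membership, the Type-I and Type-II sums of squares for the Age
    term agree.
    """
    _check_design(sub_table)
    df = sub_table.rename(columns={parameter: "_y"})
    model = smf.ols("_y ~ C(group) + age + C(group):age", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=1)
    return float(table.loc["age", "sum_sq"])


def orthogonalize_age(sub_table: pd.DataFrame) -> pd.DataFrame:
    """Residualize age against group membership (helper for cross-checks)."""
    df = sub_table.copy()
    x = pd.get_dummies(df["group"], drop_first=False).astype(float)
    beta = np.linalg.lstsq(x.to_numpy(), df["age"].to_numpy(), rcond=None)[0]
    df["age"] = df["age"].to_numpy() - x.to_numpy() @ beta
    return df
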