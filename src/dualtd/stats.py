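"""Statistical battery for the simulated experiments.

Thin, typed wrappers around scipy / pingouin / statsmodels that return
uniform :class:`TestReport` records, flag degenerate inputs (zero
variance) explicitly instead of emitting NaN surprises, and enforce the
balanced designs the simulations produce.

The battery mirrors the analyses used on the simulated data: one-sample
t-tests of session scores against zero (any preference?), unpaired
t-tests for the 8th-session blockade contrast, paired t-tests for
cue-vs-reward TD errors, a mixed ANOVA (session as the repeated measure,
condition or stimulus as the between factor) for TD-error trajectories,
and a 3-way ANOVA (group x condition x port) for SR choice counts.

No multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "one_sample_ttest",
    "unpaired_ttest",
    "paired_ttest",
    "mixed_anova",
    "three_way_anova",
]


@dataclass(frozen=True)
class TestReport:
    """One statistical test result.

    ``df`` is a string so that both t-tests ("19") and F-tests ("1, 76")
    render uniformly.  ``degenerate`` marks tests whose assumptions
    collapsed (e.g. zero variance); their statistic/p-value are NaN.
    """

    name: str
    statistic: float
    df: str
    p_value: float
    description: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.name, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "description": self.description,
            "degenerate": self.degenerate,
        }


def _degenerate(name: str, description: str) -> TestReport:
    return TestReport(name=name, statistic=float("nan"), df="",
                      p_value=float("nan"), description=description,
                      degenerate=True)


def one_sample_ttest(scores: Sequence[float], mu0: float = 0.0,
                     description: str = "") -> TestReport:
    """Two-sided one-sample t-test of replicate scores against ``mu0``."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.allclose(x.std(ddof=1), 0.0):
        return _degenerate("one-sample t", f"zero variance; {description}")
    t, p = sps.ttest_1samp(x, mu0)
    return TestReport("one-sample t", float(t), str(x.size - 1), float(p),
                      description)


def unpaired_ttest(a: Sequence[float], b: Sequence[float],
                   welch: bool = False, description: str = "") -> TestReport:
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_sd = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if np.allclose(pooled_sd, 0.0):
        return _degenerate("unpaired t", f"zero pooled variance; {description}")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = (a.var(ddof=1) / a.size + b.var(ddof=1) / b.size) ** 2 / (
            (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
            + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
        )
        df_str = f"{df:.1f}"
    else:
        df_str = str(a.size + b.size - 2)
    name = "Welch t" if welch else "unpaired t"
    return TestReport(name, float(t), df_str, float(p), description)


def paired_ttest(a: Sequence[float], b: Sequence[float],
                 description: str = "") -> TestReport:
    """Two-sided paired t-test on conformal samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must be conformal")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return _degenerate("paired t", f"zero difference variance; {description}")
    t, p = sps.ttest_rel(a, b)
    return TestReport("paired t", float(t), str(a.size - 1), float(p),
                      description)


def mixed_anova(df: pd.DataFrame, dv: str, within: str, subject: str,
                between: str) -> List[TestReport]:
    """Balanced repeated-measures (mixed) ANOVA.

    ``within`` is the repeated measure (session), ``between`` the group
    factor; each subject must contribute exactly one observation per
    within level.  Returns reports for both main effects and the
    interaction.  Raises on unbalanced designs.
    """
    counts = df.groupby([subject, within], observed=True)[dv].count()
    n_levels = df[within].nunique()
    per_subject = df.groupby(subject, observed=True)[dv].count()
    if (counts != 1).any() or (per_subject != n_levels).any():
        raise ValueError("unbalanced design: each subject needs exactly one "
                         "observation per within-factor level")
    per_group = df.groupby(between, observed=True)[subject].nunique()
    if per_group.nunique() != 1:
        raise ValueError("unbalanced design: unequal subjects per group")

    import pingouin as pg

    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between)
    reports = []
    for _, row in aov.iterrows():
        src = row["Source"]
        label = (f"{between} x {within}" if src == "Interaction" else src)
        reports.append(TestReport(
            name=f"mixed ANOVA: {label}",
            statistic=float(row["F"]),
            df=f"{int(row['DF1'])}, {int(row['DF2'])}",
            p_value=float(row["p_unc"]),
            description=f"dv={dv}, within={within}, between={between}",
        ))
    return reports


def three_way_anova(df: pd.DataFrame, dv: str = "value",
                    factors: Sequence[str] = ("group", "condition", "port"),
                    ) -> List[TestReport]:
    """Full-factorial 3-way ANOVA on a balanced 2 x 2 x 2 design.

    Returns reports for all main effects and interactions (type-II sums
    of squares; identical to type-I/III on balanced designs).  Raises on
    unbalanced cells.

    Note: when the dependent variable is the pair of port-choice counts
    that sum to a constant per replicate, every effect not involving
    ``port`` has zero sum of squares by construction; the meaningful
    group-by-condition effect on port preference is the three-way
    interaction term.
    """
    f1, f2, f3 = factors
    cells = df.groupby(list(factors), observed=True)[dv].count()
    if cells.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    work = df.rename(columns={dv: "_dv", f1: "_f1", f2: "_f2", f3: "_f3"})
    fit = smf.ols("_dv ~ _f1 * _f2 * _f3", data=work).fit()
    tab = anova_lm(fit, typ=2)
    rename = {"_f1": f1, "_f2": f2, "_f3": f3}
    reports = []
    for src, row in tab.iterrows():
        if src == "Residual":
            continue
        label = src
        for k, v in rename.items():
            label = label.replace(k, v)
        label = label.replace(":", " x ")
        reports.append(TestReport(
            name=f"3-way ANOVA: {label}",
            statistic=float(row["F"]),
            df=f"{int(row['df'])}, {int(tab.loc['Residual', 'df'])}",
            p_value=float(row["PR(>F)"]),
            description=f"dv={dv}, factors={'x'.join(factors)}",
        ))
    return reports
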