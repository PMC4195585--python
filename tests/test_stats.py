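"""Tests of the statistical battery.

t statistics are checked against hand-coded textbook formulas; both ANOVAs
are checked against independently hand-coded balanced sums-of-squares
decompositions; and type-I error rates are calibrated against the nominal
level under a simulated null.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualtd import (
    mixed_anova,
    one_sample_ttest,
    paired_ttest,
    three_way_anova,
    unpaired_ttest,
)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestOneSample:
    def test_zero_variance_flagged(self):
        rep = one_sample_ttest([0.0] * 10)
        assert rep.degenerate
        assert np.isnan(rep.p_value)

    def test_symmetric_scores_give_t_zero(self):
        rep = one_sample_ttest([-0.4, 0.4, -0.2, 0.2])
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0.5, 0.1, size=20)
        rep = one_sample_ttest(x)
        t_hand = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(x) - 1)
        assert rep.statistic == pytest.approx(t_hand, abs=1e-8)
        assert rep.p_value == pytest.approx(p_hand, abs=1e-8)
        assert rep.df == "19"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            one_sample_ttest([1.0])


class TestTwoSample:
    def test_identical_samples_degenerate(self):
        rep = unpaired_ttest([1.0] * 5, [1.0] * 5)
        assert rep.degenerate
        rep = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.degenerate

    def test_separated_groups_highly_significant(self, rng):
        a = rng.normal(0.0, 0.05, 30)
        b = rng.normal(1.0, 0.05, 30)
        assert unpaired_ttest(a, b).p_value < 1e-20

    def test_pooled_t_matches_hand_formula(self, rng):
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.3, 1.0, 12)
        rep = unpaired_ttest(a, b)
        sp2 = (11 * a.var(ddof=1) + 11 * b.var(ddof=1)) / 22
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 12))
        assert rep.statistic == pytest.approx(t_hand, abs=1e-8)
        assert rep.df == "22"

    def test_welch_variant_available(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 3, 15)
        rep = unpaired_ttest(a, b, welch=True)
        assert rep.name == "Welch t"
        t_sp, p_sp = sps.ttest_ind(a, b, equal_var=False)
        assert rep.statistic == pytest.approx(float(t_sp), abs=1e-10)

    def test_paired_matches_one_sample_on_differences(self, rng):
        a = rng.normal(0.2, 0.5, 15)
        b = rng.normal(0.0, 0.5, 15)
        rep = paired_ttest(a, b)
        ref = one_sample_ttest(a - b)
        assert rep.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert rep.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_nonconformal_paired_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Mixed (repeated-measures) ANOVA
# ---------------------------------------------------------------------------

def mixed_anova_oracle(df, dv, within, subject, between):
    """Hand-coded balanced two-way mixed ANOVA sums of squares.

    Between-subjects F uses the subjects-within-groups mean square; the
    within factor and interaction use the residual (subject x within)
    mean square.
    """
    grand = df[dv].mean()
    groups = sorted(df[between].unique())
    times = sorted(df[within].unique())
    subjects = df[subject].unique()
    n_g = len(groups)
    n_t = len(times)
    n_s = len(subjects) // n_g  # per group

    mu_g = df.groupby(between)[dv].mean()
    mu_t = df.groupby(within)[dv].mean()
    mu_gt = df.groupby([between, within])[dv].mean()
    mu_s = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()

    ss_a = n_s * n_t * sum((mu_g[g] - grand) ** 2 for g in groups)
    ss_subj = n_t * sum((mu_s[s] - mu_g[subj_group[s]]) ** 2 for s in subjects)
    ss_b = n_s * n_g * sum((mu_t[t] - grand) ** 2 for t in times)
    ss_ab = n_s * sum(
        (mu_gt[g, t] - mu_g[g] - mu_t[t] + grand) ** 2
        for g in groups for t in times
    )
    ss_tot = ((df[dv] - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = n_g - 1, n_g * (n_s - 1)
    df_b = n_t - 1
    df_ab = (n_g - 1) * (n_t - 1)
    df_err = df_subj * df_b
    f_a = (ss_a / df_a) / (ss_subj / df_subj)
    f_b = (ss_b / df_b) / (ss_err / df_err)
    f_ab = (ss_ab / df_ab) / (ss_err / df_err)
    return {"between": f_a, "within": f_b, "interaction": f_ab}


def _mixed_dataset(rng, n_per_group=6, n_sessions=4, group_gap=0.0,
                   trend=0.0, interaction=0.0, noise=1.0):
    rows = []
    for gi, g in enumerate(("paired", "random")):
        for s in range(n_per_group):
            subj = f"{g}{s}"
            for t in range(n_sessions):
                mu = gi * group_gap + t * trend + gi * t * interaction
                rows.append(dict(subj=subj, cond=g, sess=t,
                                 val=mu + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_cells_give_zero_f(self, rng):
        df = _mixed_dataset(rng, noise=0.0)
        df["val"] = 1.0
        # add infinitesimal jitter so variance is not exactly zero
        df["val"] += rng.normal(0, 1e-9, len(df))
        reports = mixed_anova(df, dv="val", within="sess", subject="subj",
                              between="cond")
        for rep in reports:
            assert rep.p_value > 0.1

    def test_session_trend_without_group_difference(self, rng):
        df = _mixed_dataset(rng, trend=2.0, noise=0.3)
        reports = {r.name.split(": ")[1]: r for r in mixed_anova(
            df, dv="val", within="sess", subject="subj", between="cond")}
        assert reports["sess"].p_value < 1e-6
        assert reports["cond x sess"].p_value > 0.01

    def test_interaction_detected(self, rng):
        df = _mixed_dataset(rng, interaction=1.5, noise=0.3)
        reports = {r.name.split(": ")[1]: r for r in mixed_anova(
            df, dv="val", within="sess", subject="subj", between="cond")}
        assert reports["cond x sess"].p_value < 1e-6

    def test_matches_hand_coded_sums_of_squares(self, rng):
        df = _mixed_dataset(rng, group_gap=0.5, trend=0.4, interaction=0.2)
        reports = {r.name.split(": ")[1]: r for r in mixed_anova(
            df, dv="val", within="sess", subject="subj", between="cond")}
        oracle = mixed_anova_oracle(df, "val", "sess", "subj", "cond")
        assert reports["cond"].statistic == pytest.approx(
            oracle["between"], abs=1e-6)
        assert reports["sess"].statistic == pytest.approx(
            oracle["within"], abs=1e-6)
        assert reports["cond x sess"].statistic == pytest.approx(
            oracle["interaction"], abs=1e-6)

    def test_unbalanced_rejected(self, rng):
        df = _mixed_dataset(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df, dv="val", within="sess", subject="subj",
                        between="cond")


# ---------------------------------------------------------------------------
# Three-way ANOVA
# ---------------------------------------------------------------------------

def three_way_oracle(df, dv, factors):
    """Hand-coded balanced 2x2x2 factorial sums of squares via contrasts."""
    cells = df.groupby(list(factors))[dv].mean()
    n = df.groupby(list(factors))[dv].count().iloc[0]
    levels = [sorted(df[f].unique()) for f in factors]
    assert all(len(l) == 2 for l in levels)

    def contrast(signs):
        total = 0.0
        for i, a in enumerate(levels[0]):
            for j, b in enumerate(levels[1]):
                for k, c in enumerate(levels[2]):
                    s = 1.0
                    if signs[0]:
                        s *= (1 if i else -1)
                    if signs[1]:
                        s *= (1 if j else -1)
                    if signs[2]:
                        s *= (1 if k else -1)
                    total += s * cells[a, b, c]
        return total / 8.0

    ss = {}
    for name, signs in [
        (factors[0], (1, 0, 0)), (factors[1], (0, 1, 0)),
        (factors[2], (0, 0, 1)),
        (f"{factors[0]} x {factors[1]}", (1, 1, 0)),
        (f"{factors[0]} x {factors[2]}", (1, 0, 1)),
        (f"{factors[1]} x {factors[2]}", (0, 1, 1)),
        (f"{factors[0]} x {factors[1]} x {factors[2]}", (1, 1, 1)),
    ]:
        ss[name] = 8 * n * contrast(signs) ** 2
    ss_cells = sum(
        n * (cells[key] - df[dv].mean()) ** 2 for key in cells.index)
    ss_err = ((df[dv] - df.merge(
        cells.rename("mu"), left_on=list(factors), right_index=True)["mu"]
    ) ** 2).sum()
    df_err = len(df) - 8
    return {k: (v / 1) / (ss_err / df_err) for k, v in ss.items()}


def _factorial_dataset(rng, n=10, effects=None, noise=1.0):
    effects = effects or {}
    rows = []
    for g in ("ST", "GT"):
        for c in ("paired", "random"):
            for p in ("active", "inactive"):
                mu = 25.0
                mu += effects.get("port", 0.0) * (1 if p == "active" else -1)
                mu += effects.get("gcp", 0.0) * (
                    (1 if g == "ST" else -1) * (1 if c == "paired" else -1)
                    * (1 if p == "active" else -1))
                for r in range(n):
                    rows.append(dict(group=g, condition=c, port=p,
                                     value=mu + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestThreeWayAnova:
    def test_null_data_no_effects(self, rng):
        df = _factorial_dataset(rng)
        reports = three_way_anova(df)
        assert len(reports) == 7
        assert all(r.p_value > 0.001 for r in reports)

    def test_constructed_effects_detected(self, rng):
        df = _factorial_dataset(rng, effects={"port": 5.0, "gcp": 3.0},
                                noise=1.0)
        reports = {r.name.split(": ")[1]: r for r in three_way_anova(df)}
        assert reports["port"].p_value < 1e-10
        assert reports["group x condition x port"].p_value < 1e-10
        assert reports["group"].p_value > 0.001

    def test_matches_hand_coded_contrasts(self, rng):
        df = _factorial_dataset(rng, effects={"port": 2.0, "gcp": 1.0})
        reports = {r.name.split(": ")[1]: r for r in three_way_anova(df)}
        oracle = three_way_oracle(df, "value", ("group", "condition", "port"))
        for name, f_hand in oracle.items():
            assert reports[name].statistic == pytest.approx(f_hand, rel=1e-6)

    def test_unbalanced_rejected(self, rng):
        df = _factorial_dataset(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            three_way_anova(df)


# ---------------------------------------------------------------------------
# Type-I error calibration under the null
# ---------------------------------------------------------------------------

class TestTypeIError:
    """Each test's false-positive rate at nominal 0.05 stays inside the
    binomial confidence band when data come from a single seeded normal."""

    def _check(self, hits, n_sims):
        res = sps.binomtest(hits, n_sims, 0.05)
        assert res.pvalue > 0.01, f"type-I rate {hits}/{n_sims} off nominal"

    def test_t_tests_calibrated(self):
        rng = np.random.default_rng(2024)
        n_sims = 1000
        hits = {"one": 0, "unpaired": 0, "paired": 0}
        for _ in range(n_sims):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            if one_sample_ttest(a).p_value < 0.05:
                hits["one"] += 1
            if unpaired_ttest(a, b).p_value < 0.05:
                hits["unpaired"] += 1
            if paired_ttest(a, b).p_value < 0.05:
                hits["paired"] += 1
        for v in hits.values():
            self._check(v, n_sims)

    def test_mixed_anova_calibrated(self):
        rng = np.random.default_rng(7)
        n_sims, hits = 300, 0
        for _ in range(n_sims):
            df = _mixed_dataset(rng, n_per_group=5, n_sessions=3)
            reports = {r.name.split(": ")[1]: r for r in mixed_anova(
                df, dv="val", within="sess", subject="subj", between="cond")}
            if reports["cond x sess"].p_value < 0.05:
                hits += 1
        self._check(hits, n_sims)

    def test_three_way_anova_calibrated(self):
        rng = np.random.default_rng(8)
        n_sims, hits = 300, 0
        for _ in range(n_sims):
            df = _factorial_dataset(rng, n=5)
            reports = {r.name.split(": ")[1]: r for r in three_way_anova(df)}
            if reports["group x condition x port"].p_value < 0.05:
                hits += 1
        self._check(hits, n_sims)
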