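"""Cohort statistics: quartiles, rm-ANOVA, Pearson, group contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepsri import (
    DeltaSri,
    ParticipantSummary,
    delta_correlations,
    delta_group_ttest,
    group_compare_total_sri,
    pearson,
    quartile_stratify,
    rm_anova_week,
)


def summary(pid, w1, w2, w3, total=None, naps=None, mood=None, mental=None):
    return ParticipantSummary(
        participant_id=pid,
        weekly_sri={1: w1, 2: w2, 3: w3},
        delta=DeltaSri(
            w2_minus_w1=None if None in (w1, w2) else w2 - w1,
            w3_minus_w2=None if None in (w2, w3) else w3 - w2,
            w3_minus_w1=None if None in (w1, w3) else w3 - w1,
        ),
        total_sri=total if total is not None else (w1 if w1 is not None else None),
        weekly_nap_minutes=naps or {},
        mood_disorder=mood,
        weekly_mental_exhaustion=mental or {},
    )


def cohort_linear(n, slope=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = 60 + i
        w = [base + slope * k + noise * rng.normal() for k in range(3)]
        out.append(summary(f"P{i:03d}", *w))
    return out


# -- quartiles --------------------------------------------------------------


def test_quartile_sizes_floor():
    bottom, top = quartile_stratify(cohort_linear(99))
    assert len(bottom) == len(top) == 24


def test_quartile_n8():
    bottom, top = quartile_stratify(cohort_linear(8))
    assert len(bottom) == len(top) == 2


def test_quartile_too_small():
    with pytest.raises(ValueError, match="n >= 8"):
        quartile_stratify(cohort_linear(7))


def test_quartile_order(rng):
    cohort = []
    for i in range(40):
        w1 = float(rng.normal(75, 10))
        cohort.append(summary(f"P{i:02d}", w1, w1, w1))
    bottom, top = quartile_stratify(cohort)
    by_id = {s.participant_id: s.weekly_sri[1] for s in cohort}
    assert max(by_id[i] for i in bottom) <= min(by_id[i] for i in top)


def test_quartile_excludes_incomplete():
    cohort = cohort_linear(12)
    cohort[0].weekly_sri[3] = None  # drops to 11 complete
    bottom, top = quartile_stratify(cohort)
    assert len(bottom) == 11 // 4


# -- repeated-measures ANOVA ------------------------------------------------

# printed hand table: 4 subjects x 3 weeks
HAND_TABLE = np.array(
    [
        [70.0, 74.0, 76.0],
        [62.0, 66.0, 71.0],
        [80.0, 79.0, 83.0],
        [55.0, 60.0, 58.0],
    ]
)


def ss_oracle(Y):
    """Textbook sums-of-squares partition for one within factor."""
    n, k = Y.shape
    grand = Y.mean()
    ss_subj = k * sum((Y[i].mean() - grand) ** 2 for i in range(n))
    ss_week = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((Y - grand) ** 2).sum()
    ss_res = ss_tot - ss_subj - ss_week
    F = (ss_week / (k - 1)) / (ss_res / ((n - 1) * (k - 1)))
    return F


def _cohort_from_table(Y):
    return [summary(f"S{i}", *row) for i, row in enumerate(Y)]


def test_rm_anova_hand_table_matches_ss_oracle():
    res = rm_anova_week(_cohort_from_table(HAND_TABLE))
    assert res.estimate == pytest.approx(ss_oracle(HAND_TABLE), abs=1e-9)
    assert res.df == "(2, 6)"


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(4)
    Y = rng.normal(70, 8, (10, 3))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(10), 3),
            "week": np.tile([1, 2, 3], 10),
            "sri": Y.ravel(),
        }
    )
    ref = AnovaRM(long, "sri", "subject", within=["week"]).fit()
    res = rm_anova_week(_cohort_from_table(Y))
    assert res.estimate == pytest.approx(
        float(ref.anova_table["F Value"].iloc[0]), abs=1e-8
    )
    assert res.p_value == pytest.approx(
        float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-8
    )


def test_rm_anova_constant_weeks_F0():
    cohort = [summary(f"S{i}", 60.0 + i, 60.0 + i, 60.0 + i) for i in range(6)]
    res = rm_anova_week(cohort)
    assert res.estimate == 0.0 and res.p_value == 1.0


def test_rm_anova_null_cell_lists_ids():
    cohort = cohort_linear(5)
    cohort[2].weekly_sri[2] = None
    with pytest.raises(ValueError, match="P002"):
        rm_anova_week(cohort)


def test_rm_anova_week2_shift_only_moves_week_ss():
    """A constant added to every week-2 value moves only the week SS."""
    rng = np.random.default_rng(0)
    Y = rng.normal(0, 1, (6, 3))
    Y2 = Y.copy()
    Y2[:, 1] += 7.0
    ra = rm_anova_week(_cohort_from_table(Y))
    rb = rm_anova_week(_cohort_from_table(Y2))
    assert rb.extra["ss_subject"] == pytest.approx(ra.extra["ss_subject"], abs=1e-9)
    assert rb.extra["ss_resid"] == pytest.approx(ra.extra["ss_resid"], abs=1e-9)
    assert rb.extra["ss_week"] != pytest.approx(ra.extra["ss_week"])


# -- Pearson ----------------------------------------------------------------


def test_pearson_exact_lines():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson(x, x).estimate == pytest.approx(1.0)
    assert pearson(x, [-v for v in x]).estimate == pytest.approx(-1.0)


def test_pearson_matches_direct_formula(rng):
    x = rng.normal(size=10)
    y = 0.4 * x + rng.normal(size=10)
    res = pearson(x, y)
    r = (np.sum((x - x.mean()) * (y - y.mean()))
         / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    from scipy import stats as sps

    t = r * np.sqrt(8 / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), 8)
    assert res.estimate == pytest.approx(r, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)
    assert res.n == 10 and res.df == "8"


def test_pearson_listwise_and_errors():
    with pytest.raises(ValueError, match="n >= 3"):
        pearson([1, 2, np.nan], [1, 2, 3])
    with pytest.raises(ValueError, match="zero variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@settings(max_examples=20, deadline=None)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.1, 50),
    st.floats(-100, 100),
)
def test_pearson_affine_invariance(seed, a, b):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    r0 = pearson(x, y).estimate
    r1 = pearson(a * x + b, y).estimate
    assert r0 == pytest.approx(r1, abs=1e-9)


# -- group contrasts --------------------------------------------------------


def test_f_equals_t_squared():
    cohort = [
        summary("A1", 70, 70, 70, total=68.0, mood=True),
        summary("A2", 70, 70, 70, total=75.0, mood=True),
        summary("A3", 70, 70, 70, total=71.0, mood=True),
        summary("B1", 70, 70, 70, total=80.0, mood=False),
        summary("B2", 70, 70, 70, total=78.0, mood=False),
        summary("B3", 70, 70, 70, total=85.0, mood=False),
    ]
    res = group_compare_total_sri(cohort)
    assert res.estimate == pytest.approx(res.extra["t"] ** 2, abs=1e-9)
    assert res.p_value == pytest.approx(res.extra["p_t"], abs=1e-12)
    assert res.extra["n_group"] == 3 and res.extra["n_ref"] == 3


def test_group_too_small():
    cohort = [summary("A", 70, 70, 70, mood=True),
              summary("B", 70, 70, 70, mood=False),
              summary("C", 70, 70, 70, mood=False)]
    with pytest.raises(ValueError, match="2 members"):
        group_compare_total_sri(cohort)


def test_delta_ttest_identical_groups():
    cohort = [summary(f"P{i}", 70.0, 72.0, 74.0) for i in range(8)]
    res = delta_group_ttest(cohort, ["P0", "P1"], ["P2", "P3"])
    assert res.estimate == 0.0 and res.p_value == 1.0


def test_delta_ttest_shifted_groups():
    rng = np.random.default_rng(1)
    cohort = []
    for i in range(24):
        d = 10.0 + rng.normal(0, 6)
        cohort.append(summary(f"B{i:02d}", 60.0, 60 + d / 2, 60 + d))
    for i in range(24):
        d = rng.normal(0, 6)
        cohort.append(summary(f"T{i:02d}", 85.0, 85 + d / 2, 85 + d))
    res = delta_group_ttest(
        cohort, [f"B{i:02d}" for i in range(24)],
        [f"T{i:02d}" for i in range(24)], "w3_minus_w1",
    )
    assert res.p_value < 1e-3
    assert res.extra["mean_bottom"] > res.extra["mean_top"]
    welch = delta_group_ttest(
        cohort, [f"B{i:02d}" for i in range(24)],
        [f"T{i:02d}" for i in range(24)], "w3_minus_w1", welch=True,
    )
    assert welch.df.startswith("welch")


# -- delta correlations -----------------------------------------------------


def test_delta_correlation_exact_negative_affine():
    cohort = []
    rng = np.random.default_rng(2)
    for i in range(20):
        d = float(rng.normal(0, 5))
        naps = {1: 200.0, 2: 200.0, 3: 200.0 - 3 * d}
        cohort.append(summary(f"P{i:02d}", 70.0, 70.0, 70.0 + d, naps=naps))
    tab = delta_correlations(cohort).set_index("analysis")
    assert tab.loc["dsri_w3_w1_vs_d_nap_minutes", "estimate"] == pytest.approx(-1.0)


def test_delta_correlation_all_null_flagged():
    cohort = [summary(f"P{i}", 70.0, 71.0, 70.0 + i) for i in range(10)]
    tab = delta_correlations(cohort).set_index("analysis")
    row = tab.loc["dsri_w3_w1_vs_d_nap_minutes"]
    assert np.isnan(row["estimate"]) and row["n"] == 0


def test_benjamini_hochberg_adjusts():
    rng = np.random.default_rng(3)
    cohort = []
    for i in range(30):
        d = float(rng.normal(0, 5))
        cohort.append(
            summary(
                f"P{i:02d}", 70.0, 70.0, 70.0 + d,
                naps={1: 200.0, 2: 200.0, 3: 200.0 - 3 * d + rng.normal(0, 5)},
                mental={1: 5.0, 2: 5.0, 3: 5.0 + rng.normal()},
            )
        )
    tab = delta_correlations(cohort, bh_correct=True)
    ok = tab["p_bh"].notna()
    assert (tab.loc[ok, "p_bh"] >= tab.loc[ok, "p_value"] - 1e-12).all()
    assert (tab.loc[ok, "p_bh"] <= 1.0).all()


def test_summary_delta_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        ParticipantSummary(
            participant_id="X",
            weekly_sri={1: 70.0, 2: 75.0, 3: 80.0},
            delta=DeltaSri(w2_minus_w1=99.0, w3_minus_w2=5.0, w3_minus_w1=10.0),
        )
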