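"""Cohort-level statistics over participant SRI summaries.

The analysis battery mirrors a repeated-measures inpatient design: weekly
SRI trajectories compared by one-within-factor repeated-measures ANOVA,
baseline (week-1) quartile stratification, a mood-disorder group contrast on
total SRI (one-way ANOVA, equivalently a two-group t-test), and Pearson
correlations between week-3-minus-week-1 change scores (delta SRI vs delta
nap minutes, delta exhaustion, and arbitrary configured covariate deltas).

Missing values are handled by listwise deletion per analysis — each result
carries its own n — and no multiple-testing correction is applied by
default (a Benjamini-Hochberg switch exists for the correlation table).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sri import DeltaSri

__all__ = [
    "ParticipantSummary",
    "StatResult",
    "StatisticName",
    "quartile_stratify",
    "rm_anova_week",
    "pearson",
    "delta_correlations",
    "group_compare_total_sri",
    "delta_group_ttest",
    "summaries_to_frame",
]


class StatisticName(str, enum.Enum):
    PEARSON_R = "PEARSON_R"
    F_RM_ANOVA = "F_RM_ANOVA"
    F_ONEWAY = "F_ONEWAY"
    T_TWO_GROUP = "T_TWO_GROUP"


@dataclass(frozen=True)
class StatResult:
    """One test: estimate, two-sided p, n used, degrees of freedom."""

    statistic_name: StatisticName
    estimate: float
    p_value: float
    n: int
    df: str
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ParticipantSummary:
    """Everything the cohort analysis needs for one participant."""

    participant_id: str
    weekly_sri: dict[int, float | None]
    delta: DeltaSri
    total_sri: float | None = None
    weekly_nap_minutes: dict[int, float | None] = field(default_factory=dict)
    mood_disorder: bool | None = None
    anxiety_disorder: bool | None = None
    weekly_mental_exhaustion: dict[int, float | None] = field(default_factory=dict)
    weekly_physical_exhaustion: dict[int, float | None] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weekly_sri
        pairs = {
            "w2_minus_w1": (2, 1),
            "w3_minus_w2": (3, 2),
            "w3_minus_w1": (3, 1),
        }
        for name, (a, b) in pairs.items():
            d = getattr(self.delta, name)
            va, vb = w.get(a), w.get(b)
            if d is not None and va is not None and vb is not None:
                if abs(d - (va - vb)) > 1e-9:
                    raise ValueError(
                        f"{self.participant_id}: delta {name} inconsistent "
                        f"with weekly SRIs"
                    )


def summaries_to_frame(cohort: Iterable[ParticipantSummary]) -> pd.DataFrame:
    """Flatten summaries into one row per participant (None -> NaN)."""
    rows = []
    for s in cohort:
        row: dict = {
            "participant_id": s.participant_id,
            "total_sri": s.total_sri,
            "mood_disorder": s.mood_disorder,
            "anxiety_disorder": s.anxiety_disorder,
        }
        for k in (1, 2, 3):
            row[f"sri_w{k}"] = s.weekly_sri.get(k)
            row[f"nap_min_w{k}"] = s.weekly_nap_minutes.get(k)
            row[f"mental_exh_w{k}"] = s.weekly_mental_exhaustion.get(k)
            row[f"physical_exh_w{k}"] = s.weekly_physical_exhaustion.get(k)
        row["dsri_w2_w1"] = s.delta.w2_minus_w1
        row["dsri_w3_w2"] = s.delta.w3_minus_w2
        row["dsri_w3_w1"] = s.delta.w3_minus_w1
        row.update(s.covariates)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def quartile_stratify(
    cohort: Sequence[ParticipantSummary],
) -> tuple[list[str], list[str]]:
    """Split the week-1 SRI distribution into bottom and top quartiles.

    Restricted to complete cases (non-null SRI at weeks 1, 2 and 3).  After
    sorting by week-1 SRI ascending (ties broken by participant id), the
    bottom group is the first floor(n/4) participants and the top group the
    last floor(n/4).
    """
    complete = [
        s
        for s in cohort
        if all(s.weekly_sri.get(k) is not None for k in (1, 2, 3))
    ]
    n = len(complete)
    if n < 8:
        raise ValueError(f"quartile stratification needs n >= 8 complete cases, got {n}")
    q = n // 4
    ordered = sorted(complete, key=lambda s: (s.weekly_sri[1], s.participant_id))
    bottom = [s.participant_id for s in ordered[:q]]
    top = [s.participant_id for s in ordered[-q:]]
    return bottom, top


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def rm_anova_week(
    cohort: Sequence[ParticipantSummary],
    weeks: tuple[int, ...] = (1, 2, 3),
    correction: str | None = None,
) -> StatResult:
    """One-within-factor repeated-measures ANOVA on weekly SRI.

    Computed from sums of squares partitioned into subject, week and
    residual (subject-by-week) components:

        F = [SS_week / (k-1)] / [SS_resid / ((n-1)(k-1))]

    with df = (k-1, (n-1)(k-1)).  No sphericity correction by default;
    ``correction='gg'`` applies Greenhouse-Geisser epsilon to the df.
    Every participant must have a non-null SRI at every requested week.
    """
    bad = [
        s.participant_id
        for s in cohort
        if any(s.weekly_sri.get(k) is None for k in weeks)
    ]
    if bad:
        raise ValueError(f"null weekly SRI for participants: {bad}")
    Y = np.array([[s.weekly_sri[k] for k in weeks] for s in cohort], dtype=float)
    n, k = Y.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    grand = Y.mean()
    ss_subject = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_week = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_resid = ss_total - ss_subject - ss_week
    df1, df2 = k - 1, (n - 1) * (k - 1)
    eps = 1.0
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(Y)
    ms_week = ss_week / df1
    ms_resid = ss_resid / df2
    tiny = 1e-12 * max(1.0, ss_total)
    if ms_resid <= tiny:
        # degenerate: no subject-by-week variation left
        F, p = (0.0, 1.0) if ss_week <= tiny else (math.inf, 0.0)
    else:
        F = ms_week / ms_resid
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return StatResult(
        statistic_name=StatisticName.F_RM_ANOVA,
        estimate=float(F),
        p_value=float(p),
        n=n,
        df=f"({df1 * eps:g}, {df2 * eps:g})",
        extra={
            "ss_subject": float(ss_subject),
            "ss_week": float(ss_week),
            "ss_resid": float(ss_resid),
            "epsilon": float(eps),
        },
    )


def _greenhouse_geisser_epsilon(Y: np.ndarray) -> float:
    S = np.cov(Y, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def pearson(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with a two-sided p from the t transform (n-2 df).

    Pairs with a missing member are dropped listwise; at least 3 complete
    pairs are required and either vector with zero variance is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a vector has zero variance")
    r, p = sps.pearsonr(x, y)
    return StatResult(
        statistic_name=StatisticName.PEARSON_R,
        estimate=float(r),
        p_value=float(p),
        n=n,
        df=f"{n - 2}",
    )


_DELTA_SPECS = {
    "nap_minutes": ("nap_min_w3", "nap_min_w1"),
    "mental_exhaustion": ("mental_exh_w3", "mental_exh_w1"),
    "physical_exhaustion": ("physical_exh_w3", "physical_exh_w1"),
}


def delta_correlations(
    cohort: Sequence[ParticipantSummary],
    extra_covariate_deltas: dict[str, tuple[str, str]] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of delta SRI (w3-w1) against clinical deltas.

    Built-in rows: delta nap minutes, delta mental exhaustion, delta
    physical exhaustion.  ``extra_covariate_deltas`` maps a label to a pair
    of covariate column names (late, early) whose difference is correlated
    the same way.  Rows with fewer than 3 complete pairs are flagged null
    rather than raising.  ``bh_correct`` adds Benjamini-Hochberg adjusted
    p-values across the emitted rows.
    """
    df = summaries_to_frame(cohort)
    dsri = df["dsri_w3_w1"].to_numpy(dtype=float)
    specs = dict(_DELTA_SPECS)
    if extra_covariate_deltas:
        specs.update(extra_covariate_deltas)
    rows = []
    for label, (late, early) in specs.items():
        if late not in df.columns or early not in df.columns:
            dvar = np.full(len(df), np.nan)
        else:
            dvar = df[late].to_numpy(dtype=float) - df[early].to_numpy(dtype=float)
        keep = ~(np.isnan(dsri) | np.isnan(dvar))
        row = {"analysis": f"dsri_w3_w1_vs_d_{label}"}
        try:
            res = pearson(dsri[keep], dvar[keep])
            row.update(
                estimate=res.estimate, p_value=res.p_value, n=res.n, df=res.df
            )
        except ValueError:
            row.update(estimate=np.nan, p_value=np.nan, n=int(keep.sum()), df="")
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_correct:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def group_compare_total_sri(
    cohort: Sequence[ParticipantSummary],
    grouping: str = "mood_disorder",
) -> StatResult:
    """Two-group contrast of total SRI (mood disorder vs none, by default).

    Reported as a one-way ANOVA F with the equivalent pooled two-sample t
    (F = t^2) and group means/SDs in ``extra``.  Listwise on total SRI and
    the grouping flag.
    """
    g1, g0 = [], []
    for s in cohort:
        flag = getattr(s, grouping, None)
        if flag is None and grouping in s.covariates:
            flag = bool(s.covariates[grouping])
        if s.total_sri is None or flag is None:
            continue
        (g1 if flag else g0).append(s.total_sri)
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 members")
    F, p = sps.f_oneway(g1, g0)
    t, pt = sps.ttest_ind(g1, g0, equal_var=True)
    return StatResult(
        statistic_name=StatisticName.F_ONEWAY,
        estimate=float(F),
        p_value=float(p),
        n=len(g1) + len(g0),
        df=f"(1, {len(g1) + len(g0) - 2})",
        extra={
            "t": float(t),
            "p_t": float(pt),
            "mean_group": float(np.mean(g1)),
            "sd_group": float(np.std(g1, ddof=1)),
            "mean_ref": float(np.mean(g0)),
            "sd_ref": float(np.std(g0, ddof=1)),
            "n_group": len(g1),
            "n_ref": len(g0),
        },
    )


def delta_group_ttest(
    cohort: Sequence[ParticipantSummary],
    bottom_ids: Sequence[str],
    top_ids: Sequence[str],
    which: str = "w3_minus_w1",
    welch: bool = False,
) -> StatResult:
    """Two-sided two-sample t-test of a delta SRI between SRI quartiles.

    ``which`` selects the change score (``w2_minus_w1``, ``w3_minus_w2`` or
    ``w3_minus_w1``); pooled variance unless ``welch``.
    """
    by_id = {s.participant_id: s for s in cohort}
    xs = [
        getattr(by_id[i].delta, which)
        for i in bottom_ids
        if i in by_id and getattr(by_id[i].delta, which) is not None
    ]
    ys = [
        getattr(by_id[i].delta, which)
        for i in top_ids
        if i in by_id and getattr(by_id[i].delta, which) is not None
    ]
    if not xs or not ys:
        raise ValueError("both quartile groups need a non-null delta")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if not welch and np.ptp(np.concatenate([x - x.mean(), y - y.mean()])) == 0:
        if abs(x.mean() - y.mean()) < 1e-12:
            return StatResult(StatisticName.T_TWO_GROUP, 0.0, 1.0,
                              len(x) + len(y), f"{len(x) + len(y) - 2}")
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    df = (
        f"{len(x) + len(y) - 2}"
        if not welch
        else f"welch~{_welch_df(x, y):.2f}"
    )
    return StatResult(
        statistic_name=StatisticName.T_TWO_GROUP,
        estimate=float(t),
        p_value=float(p),
        n=len(x) + len(y),
        df=df,
        extra={"mean_bottom": float(x.mean()), "mean_top": float(y.mean())},
    )


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
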