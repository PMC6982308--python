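"""Model/Results surface tying the pipeline stages together.

``SleepRegularityModel`` holds a cohort of epoch series plus covariates and
policies; ``fit()`` runs scoring -> eligibility filtering -> SRI (total,
weekly, deltas) -> nap aggregation and returns a
``SleepRegularityResults`` object carrying the per-participant summary
table, the statistical battery (quartile trajectories, mood-disorder
contrast, delta correlations) and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EpochSeries
from .scoring import ScoringPolicy, detect_bouts, score_states, weekly_nap_minutes
from .sri import (
    DropReason,
    FilterPolicy,
    SriResult,
    Window,
    compute_sri,
    eligibility_filter,
    missingness_report,
    sri_results_frame,
    weekly_sris,
)
from .stats import (
    ParticipantSummary,
    StatResult,
    delta_correlations,
    delta_group_ttest,
    group_compare_total_sri,
    quartile_stratify,
    rm_anova_week,
    summaries_to_frame,
)

__all__ = ["SleepRegularityModel", "SleepRegularityResults"]


def _covariate_lookup(covariates: pd.DataFrame | None) -> dict[str, dict]:
    if covariates is None or covariates.empty:
        return {}
    return {
        str(row["participant_id"]): row.to_dict()
        for _, row in covariates.iterrows()
    }


class SleepRegularityModel:
    """Sleep-regularity analysis of an actigraphy cohort.

    Parameters
    ----------
    cohort
        Epoch series, one per participant.  States may be unscored; scoring
        is applied during ``fit`` unless ``use_truth_states``.
    covariates
        Optional per-participant table with ``participant_id`` and any of:
        ``mood_disorder``, ``anxiety_disorder``,
        ``{mental,physical}_exhaustion_w{1,2,3}`` plus arbitrary numeric
        covariate columns.
    scoring, filter_policy
        Policies for the activity scorer and the eligibility filter.
    sri_mode
        ``'daily'`` (average of per-day-pair agreements, default) or
        ``'pooled'`` (all valid epoch pairs weighted equally).
    """

    def __init__(
        self,
        cohort: Sequence[EpochSeries],
        covariates: pd.DataFrame | None = None,
        scoring: ScoringPolicy | None = None,
        filter_policy: FilterPolicy | None = None,
        sri_mode: str = "daily",
    ) -> None:
        self.cohort = list(cohort)
        self.covariates = covariates
        self.scoring = scoring or ScoringPolicy()
        self.filter_policy = filter_policy or FilterPolicy()
        if sri_mode not in ("daily", "pooled"):
            raise ValueError(f"unknown sri_mode {sri_mode!r}")
        self.sri_mode = sri_mode

    @classmethod
    def from_directory(
        cls, path, dialect: str = "plain", covariates_csv=None, **kwargs
    ) -> "SleepRegularityModel":
        """Build a model from a directory of per-participant epoch CSVs."""
        from pathlib import Path

        from .io import read_epoch_csv

        path = Path(path)
        series = [
            read_epoch_csv(p, dialect=dialect)
            for p in sorted(path.glob("*.csv"))
            if p.stem not in ("covariates", "truth", "manifest")
        ]
        cov = pd.read_csv(covariates_csv) if covariates_csv else None
        return cls(series, covariates=cov, **kwargs)

    def fit(self, use_truth_states: bool = False) -> "SleepRegularityResults":
        """Run the full pipeline and return results.

        ``use_truth_states=True`` skips activity scoring and trusts the
        states already present (generator truth, or pre-scored data).
        """
        scored: list[EpochSeries] = []
        for s in self.cohort:
            scored.append(s if use_truth_states else score_states(s, self.scoring))
        kept_ids, dropped = eligibility_filter(scored, self.filter_policy)
        kept = [s for s in scored if s.participant_id in set(kept_ids)]
        missing = missingness_report(
            scored, horizon_days=self.filter_policy.horizon_days
        )

        cov = _covariate_lookup(self.covariates)
        summaries: list[ParticipantSummary] = []
        sri_by_id: dict[str, dict[Window, SriResult]] = {}
        for s in kept:
            weekly, delta = weekly_sris(s, mode=self.sri_mode)
            total = compute_sri(s, Window.TOTAL, mode=self.sri_mode)
            sri_by_id[s.participant_id] = {
                Window.TOTAL: total,
                **{Window(f"WEEK{k}"): r for k, r in weekly.items()},
            }
            bouts = detect_bouts(s, self.scoring)
            naps = weekly_nap_minutes(bouts, s)
            c = cov.get(s.participant_id, {})

            def _flag(name: str):
                v = c.get(name)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    return None
                return bool(v)

            def _wk(prefix: str) -> dict[int, float | None]:
                out = {}
                for k in (1, 2, 3):
                    v = c.get(f"{prefix}_w{k}")
                    out[k] = (
                        None
                        if v is None or (isinstance(v, float) and np.isnan(v))
                        else float(v)
                    )
                return out

            extra = {
                k: float(v)
                for k, v in c.items()
                if k
                not in {"participant_id", "mood_disorder", "anxiety_disorder"}
                and not str(k).endswith(("_w1", "_w2", "_w3"))
                and isinstance(v, (int, float))
                and not (isinstance(v, float) and np.isnan(v))
            }
            summaries.append(
                ParticipantSummary(
                    participant_id=s.participant_id,
                    weekly_sri={k: r.sri for k, r in weekly.items()},
                    delta=delta,
                    total_sri=total.sri,
                    weekly_nap_minutes=naps,
                    mood_disorder=_flag("mood_disorder"),
                    anxiety_disorder=_flag("anxiety_disorder"),
                    weekly_mental_exhaustion=_wk("mental_exhaustion"),
                    weekly_physical_exhaustion=_wk("physical_exhaustion"),
                    covariates=extra,
                )
            )
        return SleepRegularityResults(
            model=self,
            summaries=summaries,
            sri_by_id=sri_by_id,
            kept_ids=kept_ids,
            dropped=dropped,
            missingness=missing,
        )


@dataclass
class SleepRegularityResults:
    """Fitted cohort results: tables, contrasts, and a text summary."""

    model: SleepRegularityModel
    summaries: list[ParticipantSummary]
    sri_by_id: dict[str, dict[Window, SriResult]]
    kept_ids: list[str]
    dropped: dict[str, DropReason]
    missingness: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # -- tables -------------------------------------------------------------

    @property
    def participant_table(self) -> pd.DataFrame:
        """One row per eligible participant: weekly/total SRI, deltas, naps."""
        return summaries_to_frame(self.summaries)

    def sri_table(self) -> pd.DataFrame:
        """Tidy per-participant, per-window SRI results."""
        return sri_results_frame(self.sri_by_id)

    def weekly_table(self) -> pd.DataFrame:
        """Cohort mean (SD) of the weekly variables, one row per week."""
        df = self.participant_table
        rows = []
        for k in (1, 2, 3):
            row = {"week": k}
            for label, col in [
                ("sri", f"sri_w{k}"),
                ("nap_minutes", f"nap_min_w{k}"),
                ("mental_exhaustion", f"mental_exh_w{k}"),
                ("physical_exhaustion", f"physical_exh_w{k}"),
            ]:
                if col in df.columns:
                    v = df[col].astype(float)
                    row[f"{label}_mean"] = v.mean()
                    row[f"{label}_sd"] = v.std(ddof=1)
                    row[f"{label}_n"] = int(v.notna().sum())
            rows.append(row)
        return pd.DataFrame(rows)

    # -- statistics ---------------------------------------------------------

    def quartiles(self) -> tuple[list[str], list[str]]:
        """(bottom, top) week-1 SRI quartile ids among complete cases."""
        if "quartiles" not in self._cache:
            self._cache["quartiles"] = quartile_stratify(self.summaries)
        return self._cache["quartiles"]

    def quartile_trajectories(self) -> dict[str, StatResult]:
        """Repeated-measures ANOVA of weekly SRI within each quartile."""
        bottom, top = self.quartiles()
        by_id = {s.participant_id: s for s in self.summaries}
        return {
            "bottom": rm_anova_week([by_id[i] for i in bottom]),
            "top": rm_anova_week([by_id[i] for i in top]),
        }

    def quartile_delta_tests(self) -> dict[str, StatResult]:
        """Two-group t-tests of each delta SRI between bottom and top quartiles."""
        bottom, top = self.quartiles()
        return {
            which: delta_group_ttest(self.summaries, bottom, top, which)
            for which in ("w2_minus_w1", "w3_minus_w2", "w3_minus_w1")
        }

    def mood_contrast(self) -> StatResult:
        """One-way ANOVA / t-test of total SRI by mood-disorder status."""
        return group_compare_total_sri(self.summaries, "mood_disorder")

    def delta_correlation_table(self, bh_correct: bool = False) -> pd.DataFrame:
        """Pearson correlations of delta SRI (w3-w1) vs clinical deltas."""
        return delta_correlations(self.summaries, bh_correct=bh_correct)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the whole analysis."""
        lines = []
        n_in = len(self.model.cohort)
        lines.append("Sleep Regularity Index cohort analysis")
        lines.append("=" * 42)
        lines.append(
            f"Participants: {n_in} recorded, {len(self.kept_ids)} eligible, "
            f"{len(self.dropped)} dropped"
        )
        for reason in DropReason:
            ids = [i for i, r in self.dropped.items() if r is reason]
            if ids:
                lines.append(f"  dropped {reason.value}: {', '.join(ids)}")
        lines.append("")
        lines.append("Missingness sensitivity (participants with >= h excluded")
        lines.append("hours on any day within the horizon):")
        for _, r in self.missingness.iterrows():
            lines.append(
                f"  >= {r['threshold_hours']:.0f} h: {int(r['n_participants'])}"
            )
        df = self.participant_table
        if not df.empty:
            tot = df["total_sri"].astype(float)
            lines.append("")
            lines.append(
                f"Total SRI: mean {tot.mean():.2f} (SD {tot.std(ddof=1):.2f}), "
                f"range {tot.min():.2f}-{tot.max():.2f}, n={int(tot.notna().sum())}"
            )
            wk = self.weekly_table()
            lines.append("Weekly SRI, mean (SD):")
            for _, r in wk.iterrows():
                if not np.isnan(r.get("sri_mean", np.nan)):
                    lines.append(
                        f"  week {int(r['week'])}: {r['sri_mean']:.2f} "
                        f"({r['sri_sd']:.2f}), n={int(r['sri_n'])}"
                    )
        try:
            traj = self.quartile_trajectories()
            lines.append("")
            lines.append("Week-1 SRI quartile trajectories (rm-ANOVA on weeks 1-3):")
            for grp, res in traj.items():
                lines.append(
                    f"  {grp} quartile: F{res.df} = {res.estimate:.2f}, "
                    f"p = {res.p_value:.4g}, n = {res.n}"
                )
            for which, res in self.quartile_delta_tests().items():
                lines.append(
                    f"  delta {which}: t = {res.estimate:.2f}, "
                    f"p = {res.p_value:.4g}, n = {res.n}"
                )
        except ValueError as e:
            lines.append(f"  quartile analysis unavailable: {e}")
        try:
            mood = self.mood_contrast()
            lines.append("")
            lines.append(
                "Mood-disorder contrast on total SRI (one-way ANOVA): "
                f"F{mood.df} = {mood.estimate:.2f}, p = {mood.p_value:.4g}, "
                f"n = {mood.n}"
            )
            lines.append(
                f"  mood mean {mood.extra['mean_group']:.2f} "
                f"(SD {mood.extra['sd_group']:.2f}, n={mood.extra['n_group']}) vs "
                f"no-mood {mood.extra['mean_ref']:.2f} "
                f"(SD {mood.extra['sd_ref']:.2f}, n={mood.extra['n_ref']})"
            )
        except ValueError as e:
            lines.append(f"  mood contrast unavailable: {e}")
        corr = self.delta_correlation_table()
        lines.append("")
        lines.append("Delta correlations (delta SRI w3-w1 vs):")
        for _, r in corr.iterrows():
            if np.isnan(r["estimate"]):
                lines.append(f"  {r['analysis']}: insufficient data (n={r['n']})")
            else:
                lines.append(
                    f"  {r['analysis']}: r = {r['estimate']:.3f}, "
                    f"p = {r['p_value']:.4g}, n = {r['n']}"
                )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_weekly_trajectories(self, ax=None):
        """Line plot of each participant's weekly SRI with quartile means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.participant_table
        weeks = [1, 2, 3]
        for _, row in df.iterrows():
            ax.plot(
                weeks,
                [row[f"sri_w{k}"] for k in weeks],
                color="0.8",
                lw=0.5,
                zorder=1,
            )
        try:
            bottom, top = self.quartiles()
            for ids, color, label in [
                (bottom, "tab:red", "bottom quartile"),
                (top, "tab:blue", "top quartile"),
            ]:
                sub = df[df["participant_id"].isin(ids)]
                ax.plot(
                    weeks,
                    [sub[f"sri_w{k}"].mean() for k in weeks],
                    color=color,
                    lw=2,
                    marker="o",
                    label=label,
                    zorder=2,
                )
            ax.legend()
        except ValueError:
            pass
        ax.set_xlabel("week")
        ax.set_ylabel("SRI")
        ax.set_xticks(weeks)
        return ax

    def plot_delta_scatter(self, against: str = "nap_minutes", ax=None):
        """Scatter of delta SRI (w3-w1) vs a clinical delta."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.participant_table
        cols = {
            "nap_minutes": ("nap_min_w3", "nap_min_w1"),
            "mental_exhaustion": ("mental_exh_w3", "mental_exh_w1"),
            "physical_exhaustion": ("physical_exh_w3", "physical_exh_w1"),
        }
        late, early = cols[against]
        x = df["dsri_w3_w1"].astype(float)
        y = df[late].astype(float) - df[early].astype(float)
        ax.scatter(x, y, s=15)
        ax.set_xlabel("delta SRI (week 3 - week 1)")
        ax.set_ylabel(f"delta {against} (week 3 - week 1)")
        return ax
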