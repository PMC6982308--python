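"""Shared fixtures: compact builders for epoch series and cohort summaries."""

from datetime import datetime

import numpy as np
import pytest

from sleepsri import DeltaSri, EpochSeries, ParticipantSummary

START = datetime(2024, 1, 8, 12, 0)


def make_series(
    states,
    activity=None,
    participant_id="T0",
    start=START,
    epoch_seconds=60,
):
    """EpochSeries from a state-code array (0 WAKE, 1 SLEEP, 2 EXCLUDED)."""
    states = np.asarray(states, dtype=np.int8)
    if activity is None:
        activity = np.where(states == 0, 500, 0)
    off = states == 2
    return EpochSeries(
        participant_id=participant_id,
        start=start,
        activity=np.asarray(activity, dtype=np.int64),
        state=states,
        off_wrist=off,
        epoch_seconds=epoch_seconds,
    )


def day_pattern(sleep_start_min, sleep_len_min, P=1440):
    """One day of states: WAKE except SLEEP in [start, start+len) minutes."""
    day = np.zeros(P, dtype=np.int8)
    i0, i1 = sleep_start_min, sleep_start_min + sleep_len_min
    day[i0:min(i1, P)] = 1
    if i1 > P:  # wrap into next day is the caller's business
        pass
    return day


def summaries_from_truth(truth, covariates=None, nap_minutes=None):
    """ParticipantSummary rows from a generator truth table.

    ``nap_minutes``: optional dict participant_id -> {week: minutes}.
    """
    cov_by_id = {}
    if covariates is not None:
        cov_by_id = {
            str(r["participant_id"]): r for _, r in covariates.iterrows()
        }
    out = []
    for _, t in truth.iterrows():
        w = {k: t[f"truth_sri_w{k}"] for k in (1, 2, 3)}
        d = DeltaSri(
            w2_minus_w1=None if w[2] is None or w[1] is None else w[2] - w[1],
            w3_minus_w2=None if w[3] is None or w[2] is None else w[3] - w[2],
            w3_minus_w1=None if w[3] is None or w[1] is None else w[3] - w[1],
        )
        pid = str(t["participant_id"])
        c = cov_by_id.get(pid, {})
        wk_exh = {
            kind: {
                k: (
                    float(c[f"{kind}_exhaustion_w{k}"])
                    if f"{kind}_exhaustion_w{k}" in c
                    else None
                )
                for k in (1, 2, 3)
            }
            for kind in ("mental", "physical")
        }
        out.append(
            ParticipantSummary(
                participant_id=pid,
                weekly_sri=w,
                delta=d,
                total_sri=t["truth_sri_total"],
                weekly_nap_minutes=(nap_minutes or {}).get(pid, {}),
                mood_disorder=bool(c["mood_disorder"])
                if "mood_disorder" in c
                else bool(t.get("mood_disorder", False)),
                weekly_mental_exhaustion=wk_exh["mental"],
                weekly_physical_exhaustion=wk_exh["physical"],
            )
        )
    return out


@pytest.fixture
def two_identical_days():
    day = day_pattern(690, 420)  # sleep 23:30-06:30 starting from noon
    return make_series(np.concatenate([day, day]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240108)
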