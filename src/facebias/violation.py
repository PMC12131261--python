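"""Violation-of-expectation analysis for the sequence experiment.

For each trial, an ordinary least-squares line is fitted to the
looking times at the five initial same-expression images (at least
four must be present) and extrapolated to position 6 to give the
looking time expected had the sequence continued. The observed
sixth-image (sequence-violating) looking time is compared with the
prediction: a paired t-test across trials for the population analysis,
and a per-trial binary "looked longer than expected" score for the
composite. Predictions may be negative for steeply declining
sequences; they are retained (not clipped) so the paired test stays
unbiased, and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, SchemaError
from .results import TTestResult

__all__ = [
    "predict_final_look",
    "violation_binary",
    "build_violation_records",
    "violation_test",
]

LOOK_COLUMNS = [f"look{i}_s" for i in range(1, 6)]


def predict_final_look(times, positions=None) -> float:
    """Extrapolate the initial-sequence looking trend to position 6.

    ``times`` are looking seconds at the initial images; missing looks
    may be given as NaN (with the default positions 1..5) or omitted by
    passing explicit ``positions``. At least four present looks are
    required — the study's inclusion rule.
    """
    y = np.asarray(times, float)
    if positions is None:
        if len(y) != 5:
            raise ValueError("expected five positions (pass `positions` otherwise)")
        x = np.arange(1.0, 6.0)
    else:
        x = np.asarray(positions, float)
        if len(x) != len(y):
            raise ValueError("times and positions must have equal length")
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    if len(y) < 4:
        raise DegenerateInputError(
            f"need at least 4 present looks to fit the trend (got {len(y)})")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept + slope * 6.0)


def violation_binary(observed_s: float, predicted_s: float) -> int:
    """1 iff the observed final look strictly exceeds the prediction."""
    return int(observed_s > predicted_s)


def build_violation_records(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial violation records for includable sequence trials.

    Returns columns trial_id, subject_id, group_id, predicted_s,
    observed_s, excess_s (= observed - predicted), exceeds (binary),
    and negative_prediction (flag).
    """
    needed = {"subject_id", "look6_s", "includable", *LOOK_COLUMNS}
    missing = needed - set(trials.columns)
    if missing:
        raise SchemaError(f"sequence trial table missing column(s): {sorted(missing)}")
    t = trials[trials["includable"].astype(bool)]
    rows = []
    for _, tr in t.iterrows():
        pred = predict_final_look([tr[c] for c in LOOK_COLUMNS])
        obs = float(tr["look6_s"])
        rows.append({
            "trial_id": tr.get("trial_id", ""),
            "subject_id": tr["subject_id"],
            "group_id": tr.get("group_id", ""),
            "predicted_s": pred,
            "observed_s": obs,
            "excess_s": obs - pred,
            "exceeds": violation_binary(obs, pred),
            "negative_prediction": pred < 0,
        })
    return pd.DataFrame(rows, columns=["trial_id", "subject_id", "group_id",
                                       "predicted_s", "observed_s", "excess_s",
                                       "exceeds", "negative_prediction"])


def violation_test(records: pd.DataFrame) -> TTestResult:
    """Paired t-test of observed vs predicted sixth-image looking times."""
    if len(records) < 2:
        raise DegenerateInputError("paired t-test requires at least 2 trials")
    obs = records["observed_s"].to_numpy(float)
    pred = records["predicted_s"].to_numpy(float)
    d = obs - pred
    if np.ptp(d) == 0:
        raise DegenerateInputError("paired t-test undefined: constant differences")
    res = stats.ttest_rel(obs, pred)
    return TTestResult(
        statistic=float(res.statistic), df=int(len(d) - 1),
        p_value=float(res.pvalue), sample_mean=float(d.mean()),
        null_value=0.0, n=len(d),
    )
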