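"""Composite facial-expression-processing scores.

Each trial yields a raw performance score: the absolute attention bias
|p - 0.5| for expression-vs-neutral trials (bias toward and away from
an expression both indicate discrimination), the signed bias p for the
intensity trials, and the binary looked-longer-than-expected outcome
for sequence trials. Raw scores are z-standardized within trial type
(pooling trials across subjects, sample SD), averaged within trial
type per subject, and those type means averaged across the subject's
trial types to give the composite. Subjects contribute only with at
least ``min_trials`` trials in total (default 3, from any experiment).

Because z-scores are invariant to positive affine rescaling of the raw
scores within a type, the composite does not depend on, e.g., whether
the absolute bias is scored as |p - 0.5| or 2|p - 0.5|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "trial_raw_score",
    "build_trial_scores",
    "standardize_by_trial_type",
    "composite_scores",
]

logger = logging.getLogger(__name__)


def trial_raw_score(experiment: str, value: float) -> float:
    """Raw composite-contributing score for a single trial.

    exp1: absolute attention bias |p - 0.5|; exp2: attention bias p;
    exp3: binary violation outcome.
    """
    if experiment == "exp1":
        return abs(float(value) - 0.5)
    if experiment == "exp2":
        return float(value)
    if experiment == "exp3":
        return float(int(bool(value)))
    raise ValidationError(f"unknown experiment tag {experiment!r}")


def build_trial_scores(exp1_bias: "pd.DataFrame | None" = None,
                       exp2_bias: "pd.DataFrame | None" = None,
                       exp3_records: "pd.DataFrame | None" = None) -> pd.DataFrame:
    """Long table of per-trial raw scores with their trial types.

    Trial types: one per expression for exp1 (e.g. ``exp1:scream``),
    one per intensity level for exp2 (e.g. ``exp2:0.5``), and a single
    type for all exp3 trials.
    """
    parts = []
    if exp1_bias is not None and len(exp1_bias):
        if "expression" not in exp1_bias or "bias_p" not in exp1_bias:
            raise SchemaError("exp1 bias table needs expression and bias_p")
        parts.append(pd.DataFrame({
            "subject_id": exp1_bias["subject_id"],
            "trial_type": "exp1:" + exp1_bias["expression"].astype(str),
            "raw": (exp1_bias["bias_p"] - 0.5).abs(),
        }))
    if exp2_bias is not None and len(exp2_bias):
        if "intensity" not in exp2_bias or "bias_p" not in exp2_bias:
            raise SchemaError("exp2 bias table needs intensity and bias_p")
        parts.append(pd.DataFrame({
            "subject_id": exp2_bias["subject_id"],
            "trial_type": "exp2:" + exp2_bias["intensity"].map("{:g}".format),
            "raw": exp2_bias["bias_p"],
        }))
    if exp3_records is not None and len(exp3_records):
        if "exceeds" not in exp3_records:
            raise SchemaError("exp3 record table needs the exceeds column")
        parts.append(pd.DataFrame({
            "subject_id": exp3_records["subject_id"],
            "trial_type": "exp3",
            "raw": exp3_records["exceeds"].astype(float),
        }))
    if not parts:
        return pd.DataFrame(columns=["subject_id", "trial_type", "raw"])
    return pd.concat(parts, ignore_index=True)


def standardize_by_trial_type(scores: pd.DataFrame, min_per_type: int = 2):
    """z-standardize raw scores within each trial type (sample SD).

    Trial types with fewer than ``min_per_type`` trials or zero
    variance cannot be standardized; they are dropped with a logged
    warning. Returns ``(scores_with_z, dropped_types)``.
    """
    missing = {"subject_id", "trial_type", "raw"} - set(scores.columns)
    if missing:
        raise SchemaError(f"score table missing column(s): {sorted(missing)}")
    scores = scores.copy()
    dropped = []
    zs = []
    for ttype, grp in scores.groupby("trial_type", sort=False):
        raw = grp["raw"].to_numpy(float)
        sd = raw.std(ddof=1) if len(raw) >= 2 else 0.0
        if len(raw) < min_per_type or sd == 0.0 or not np.isfinite(sd):
            dropped.append(ttype)
            continue
        z = (raw - raw.mean()) / sd
        zs.append(pd.Series(z, index=grp.index))
    if dropped:
        logger.warning("dropped trial type(s) with too few trials or zero "
                       "variance: %s", dropped)
    if not zs:
        out = scores.iloc[0:0].copy()
        out["z"] = pd.Series(dtype=float)
        return out, dropped
    z_all = pd.concat(zs)
    out = scores.loc[z_all.index].copy()
    out["z"] = z_all
    return out.reset_index(drop=True), dropped


def composite_scores(scores: pd.DataFrame, min_trials: int = 3,
                     aggregation: str = "by_type") -> pd.DataFrame:
    """Per-subject composite scores from standardized trial scores.

    ``aggregation="by_type"`` (default) averages z within each trial
    type per subject, then averages those type means;
    ``"by_trial"`` averages all of a subject's z-scores directly.
    Subjects with fewer than ``min_trials`` contributing trials are
    omitted (and counted in the log).
    """
    if "z" not in scores.columns:
        raise SchemaError("scores must be standardized first (missing z column)")
    if aggregation not in ("by_type", "by_trial"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    rows = []
    n_omitted = 0
    for sid, grp in scores.groupby("subject_id", sort=True):
        n_trials = len(grp)
        if n_trials < min_trials:
            n_omitted += 1
            continue
        if aggregation == "by_type":
            score = grp.groupby("trial_type")["z"].mean().mean()
        else:
            score = grp["z"].mean()
        rows.append({"subject_id": sid, "score": float(score),
                     "n_trials": int(n_trials),
                     "n_types": int(grp["trial_type"].nunique())})
    if n_omitted:
        logger.info("%d subject(s) omitted with fewer than %d trials",
                    n_omitted, min_trials)
    return pd.DataFrame(rows, columns=["subject_id", "score", "n_trials",
                                       "n_types"])
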