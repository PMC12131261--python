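"""Attention-bias statistics for the paired-presentation experiments.

The per-trial attention bias is the time spent looking at the
expression as a proportion of total looking at both images. The
population analyses are (i) one-sample t-tests of each expression's
bias against 0.5 (the indifference point), (ii) a linear mixed model of
bias on expression type with random intercepts for social group and
subject, with Tukey-adjusted pairwise contrasts of the estimated
marginal means, and (iii) a linear mixed model of bias on threat
intensity as a continuous covariate (same random-effect structure).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, SchemaError, ValidationError
from .lmm import MixedModelResult, fit_mixed_model
from .results import TTestResult

__all__ = [
    "bias_proportion",
    "compute_bias",
    "test_bias_vs_half",
    "fit_expression_lmm",
    "fit_intensity_lmm",
    "pairwise_expression_contrasts",
    "ContrastResult",
]


def bias_proportion(look_expression_s: float, look_neutral_s: float) -> float:
    """Proportion of looking time directed at the expression."""
    if look_expression_s < 0 or look_neutral_s < 0:
        raise ValidationError("looking times must be >= 0")
    total = look_expression_s + look_neutral_s
    if total <= 0:
        raise ValidationError(
            "attention bias undefined: zero total looking time "
            "(trial should have been excluded)")
    return look_expression_s / total


def compute_bias(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial attention-bias records for includable paired trials.

    Expects assembled trials with look_expression_s / look_neutral_s
    and an ``includable`` flag; raises if a flagged-includable trial
    has a zero denominator (inconsistent upstream filtering).
    """
    required = {"subject_id", "look_expression_s", "look_neutral_s", "includable"}
    missing = required - set(trials.columns)
    if missing:
        raise SchemaError(f"trial table missing column(s): {sorted(missing)}")
    t = trials[trials["includable"].astype(bool)].copy()
    total = t["look_expression_s"] + t["look_neutral_s"]
    if (total <= 0).any() or (t[["look_expression_s", "look_neutral_s"]] <= 0).any().any():
        bad = t.loc[(t["look_expression_s"] <= 0) | (t["look_neutral_s"] <= 0),
                    "trial_id"].tolist()
        raise ValidationError(
            f"includable trial(s) with a zero looking time: {bad[:5]}")
    t["bias_p"] = t["look_expression_s"] / total
    return t


def test_bias_vs_half(biases) -> TTestResult:
    """Two-sided one-sample t-test of bias proportions against 0.5."""
    x = np.asarray(biases, float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise DegenerateInputError("one-sample t-test requires n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateInputError("one-sample t-test undefined for constant data")
    res = stats.ttest_1samp(x, popmean=0.5)
    return TTestResult(
        statistic=float(res.statistic), df=int(n - 1),
        p_value=float(res.pvalue), sample_mean=float(x.mean()),
        null_value=0.5, n=n,
    )


def _check_records(records: pd.DataFrame, needed):
    missing = set(needed) - set(records.columns)
    if missing:
        raise SchemaError(f"bias records missing column(s): {sorted(missing)}")


def fit_expression_lmm(records: pd.DataFrame, reml: bool = True,
                       variance_components=None) -> MixedModelResult:
    """Mixed model of attention bias on expression type.

    Random intercepts for social group and subject (subjects are
    nested within groups). Satterthwaite df throughout.
    """
    _check_records(records, ["bias_p", "expression", "group_id", "subject_id"])
    if records["expression"].nunique() < 2:
        raise DegenerateInputError(
            "expression model needs at least two expression levels")
    res = fit_mixed_model(records, "bias_p ~ C(expression)",
                          random=("group_id", "subject_id"), reml=reml,
                          variance_components=variance_components)
    res.metadata["response"] = "bias_p"
    res.metadata["expression_levels"] = sorted(records["expression"].unique())
    return res


def fit_intensity_lmm(records: pd.DataFrame, reml: bool = True,
                      variance_components=None) -> MixedModelResult:
    """Mixed model of attention bias on continuous expression intensity.

    Intensity is on the 0.25-1.0 proportion scale (recorded in the
    metadata since the scale sets the slope's units).
    """
    _check_records(records, ["bias_p", "intensity", "group_id", "subject_id"])
    if records["intensity"].nunique() < 2:
        raise DegenerateInputError(
            "intensity model needs at least two intensity values")
    res = fit_mixed_model(records, "bias_p ~ intensity",
                          random=("group_id", "subject_id"), reml=reml,
                          variance_components=variance_components)
    res.metadata["response"] = "bias_p"
    res.metadata["intensity_scale"] = "proportion (0.25-1.0)"
    return res


@dataclass(frozen=True)
class ContrastResult:
    """A pairwise difference of estimated marginal means."""

    pair: str
    estimate: float
    std_error: float
    df: float
    t_value: float
    p_value: float          # Tukey-adjusted
    p_unadjusted: float

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def pairwise_expression_contrasts(model: MixedModelResult) -> list:
    """All pairwise contrasts of the expression estimated marginal means.

    p-values are Tukey-adjusted via the studentized range distribution
    with the contrast's Satterthwaite df (adjusted p >= unadjusted p).
    """
    pat = re.compile(r"C\(expression\)\[T\.(?P<level>[^\]]+)\]")
    terms = model.term_names
    dummy_ix = {}
    for j, name in enumerate(terms):
        m_ = pat.fullmatch(name)
        if m_:
            dummy_ix[m_.group("level")] = j
    if not dummy_ix:
        raise ValidationError("model has no expression factor")
    lvl_names = model.metadata.get(
        "expression_levels",
        sorted(dummy_ix))  # reference level carries no dummy column
    k = len(lvl_names)
    p = len(terms)

    def emm_vector(level):
        # marginal-mean weights: intercept + the level's own dummy (the
        # reference level is the intercept alone)
        v = np.zeros(p)
        v[terms.index("Intercept")] = 1.0
        if level in dummy_ix:
            v[dummy_ix[level]] = 1.0
        return v

    out = []
    for a, b in itertools.combinations(lvl_names, 2):
        c = model.contrast(emm_vector(a) - emm_vector(b))
        q = abs(c["t_value"]) * np.sqrt(2.0)
        p_tukey = float(stats.studentized_range.sf(q, k, c["df"]))
        out.append(ContrastResult(
            pair=f"{a} - {b}", estimate=c["estimate"],
            std_error=c["std_error"], df=c["df"], t_value=c["t_value"],
            p_value=min(max(p_tukey, c["p_value"]), 1.0),
            p_unadjusted=c["p_value"],
        ))
    return out
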