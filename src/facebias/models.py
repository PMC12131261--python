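"""Individual-differences models on composite scores.

The maternal-care model regresses each subject's composite
facial-expression-processing score on four maternal behaviors recorded
during infancy — grooming and cradling (percent of 30-s scan samples)
and approaching and restraining (events per 10-min focal) — plus sex
and an orthogonal quadratic polynomial in age, with random intercepts
for social group and mother. The age follow-up suite fits four models
on the larger cohort (composite + sex fixed, group random): linear
age, log(age), quadratic (orthogonal polynomial) age, and continuous
age crossed with the juvenile/adult category (juvenile = under 5
years), whose interaction model reports the juvenile slope directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError
from .lmm import MixedModelResult, fit_mixed_model

__all__ = [
    "orthogonal_poly",
    "maternal_scores",
    "fit_maternal_model",
    "fit_age_models",
    "AGE_CUTOFF_YEARS",
]

AGE_CUTOFF_YEARS = 5.0  # juvenile strictly below, adult at or above

MATERNAL_COLUMNS = ["subject_id", "n_scans", "n_groom_scans", "n_cradle_scans",
                    "approach_count", "restrain_count"]

TABLE_LABELS = {
    "Intercept": "(Intercept)",
    "grooming_score": "Grooming",
    "cradling_score": "Cradling",
    "approach_rate": "Approaching",
    "restrain_rate": "Restraining",
    "C(sex, Treatment('female'))[T.male]": "Sex (male)",
    "poly_age_1": "poly(age, 2)1",
    "poly_age_2": "poly(age, 2)2",
}


def orthogonal_poly(values, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (without the constant column).

    Columns are mutually orthogonal with unit norm and orthogonal to
    the constant — the convention under which quadratic age
    coefficients are conventionally reported. Signs are fixed so the
    degree-k column correlates positively with values**k.
    """
    x = np.asarray(values, float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(x)) < degree + 1:
        raise DegenerateInputError(
            f"need at least {degree + 1} distinct values for degree {degree}")
    X = np.vander(x, degree + 1, increasing=True)
    Q, R = np.linalg.qr(X)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q[:, 1:] * signs[1:]


def maternal_scores(maternal: pd.DataFrame, n_focals: int = 9) -> pd.DataFrame:
    """Derive analysis-scale maternal predictors from raw counts.

    Grooming/cradling become percent of scan samples; approaching/
    restraining become events per focal (using the table's ``n_focals``
    column when present). The scaling convention is recorded downstream
    in the fitted model's metadata.
    """
    missing = set(MATERNAL_COLUMNS) - set(maternal.columns)
    if missing:
        raise SchemaError(f"maternal table missing column(s): {sorted(missing)}")
    m = maternal.copy()
    if (m["n_scans"] <= 0).any():
        raise SchemaError("n_scans must be positive")
    focals = m["n_focals"] if "n_focals" in m.columns else n_focals
    m["grooming_score"] = 100.0 * m["n_groom_scans"] / m["n_scans"]
    m["cradling_score"] = 100.0 * m["n_cradle_scans"] / m["n_scans"]
    m["approach_rate"] = m["approach_count"] / focals
    m["restrain_rate"] = m["restrain_count"] / focals
    return m


def fit_maternal_model(scores: pd.DataFrame, subjects: pd.DataFrame,
                       maternal: pd.DataFrame, reml: bool = True,
                       variance_components=None) -> MixedModelResult:
    """Mixed model of composite score on maternal care, sex, and age.

    Restricted to subjects with both a composite score and maternal
    data. Fixed effects: grooming, cradling, approaching, restraining,
    sex (female reference), and an orthogonal degree-2 age polynomial;
    random intercepts for group and mother. The coefficient table is
    labeled in the conventional report shape, with significance
    asterisks at alpha = 0.05.
    """
    m = maternal_scores(maternal)
    d = (scores.merge(subjects, on="subject_id")
               .merge(m, on="subject_id"))
    if d.empty:
        raise DegenerateInputError("no subjects with both composite and maternal data")
    if (d["mother_id"].astype(str) == "").any():
        raise SchemaError("subjects with maternal data must carry a mother_id")
    basis = orthogonal_poly(d["age_years"].to_numpy(), 2)
    d = d.assign(poly_age_1=basis[:, 0], poly_age_2=basis[:, 1])
    formula = ("score ~ grooming_score + cradling_score + approach_rate + "
               "restrain_rate + C(sex, Treatment('female')) + "
               "poly_age_1 + poly_age_2")
    res = fit_mixed_model(d, formula, random=("group_id", "mother_id"),
                          reml=reml, variance_components=variance_components)
    res.fixed_effects = _relabel(res.fixed_effects).reindex(
        ["(Intercept)", "Grooming", "Cradling", "Approaching", "Restraining",
         "Sex (male)", "poly(age, 2)1", "poly(age, 2)2"])
    res.metadata.update({
        "n_subjects": int(d["subject_id"].nunique()),
        "predictor_scaling": {
            "grooming_score": "percent of scan samples",
            "cradling_score": "percent of scan samples",
            "approach_rate": "events per focal",
            "restrain_rate": "events per focal",
        },
    })
    return res


def _relabel(table: pd.DataFrame) -> pd.DataFrame:
    out = table.rename(index=TABLE_LABELS)
    out["significant"] = np.where(out["p_value"] < 0.05, "*", "")
    return out


def fit_age_models(scores: pd.DataFrame, subjects: pd.DataFrame,
                   reml: bool = True) -> dict:
    """The four age follow-up models on all scored subjects.

    Returns a dict keyed linear_age, log_age, poly_age,
    age_by_group_interaction; each value is a
    :class:`~facebias.lmm.MixedModelResult` with sex as a covariate and
    a group random intercept. The interaction model uses juveniles
    (age < 5) as the reference, so its ``age_years`` coefficient is the
    juvenile slope; the adult slope is attached as a contrast in the
    metadata.
    """
    d = scores.merge(subjects, on="subject_id").copy()
    if d.empty:
        raise DegenerateInputError("no scored subjects")
    if d["age_years"].nunique() < 2:
        raise DegenerateInputError("age is constant: age models are degenerate")
    d["log_age"] = np.log(d["age_years"].to_numpy(float))
    d["age_group"] = np.where(d["age_years"] < AGE_CUTOFF_YEARS,
                              "juvenile", "adult")
    if d["age_group"].nunique() < 2:
        raise DegenerateInputError(
            "empty age stratum: both juveniles and adults are required "
            "for the interaction model")
    basis = orthogonal_poly(d["age_years"].to_numpy(), 2)
    d = d.assign(poly_age_1=basis[:, 0], poly_age_2=basis[:, 1])

    suite = {}
    suite["linear_age"] = fit_mixed_model(
        d, "score ~ C(sex) + age_years", random=("group_id",), reml=reml)
    suite["log_age"] = fit_mixed_model(
        d, "score ~ C(sex) + log_age", random=("group_id",), reml=reml)
    suite["poly_age"] = fit_mixed_model(
        d, "score ~ C(sex) + poly_age_1 + poly_age_2", random=("group_id",),
        reml=reml)
    inter = fit_mixed_model(
        d,
        "score ~ C(sex) + age_years * C(age_group, Treatment('juvenile'))",
        random=("group_id",), reml=reml)
    # adult slope = juvenile slope + interaction
    terms = inter.term_names
    l = np.zeros(len(terms))
    l[terms.index("age_years")] = 1.0
    inter_name = "age_years:C(age_group, Treatment('juvenile'))[T.adult]"
    l[terms.index(inter_name)] = 1.0
    inter.metadata["juvenile_slope"] = inter.fixed_effects.loc["age_years"].to_dict()
    inter.metadata["adult_slope"] = inter.contrast(l)
    suite["age_by_group_interaction"] = inter
    return suite
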