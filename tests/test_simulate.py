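"""Synthetic-data generator: determinism, structure, and null behavior."""

import numpy as np
import pandas as pd
import pytest

from facebias import (
    AgeCurve, ConfigurationError, SimulationConfig, generate_cohort, generate_dataset,
    generate_exp1_trials, generate_exp2_trials, generate_exp3_trials,
    read_synthetic_dataset, write_synthetic_dataset,
)
from facebias.simulate import INTENSITIES


def test_cohort_counts_and_groups(study_dataset):
    subjects = study_dataset.subjects
    assert len(subjects) == 83
    assert subjects["group_id"].nunique() == 15
    # round-robin with jitter keeps group sizes near-balanced
    sizes = subjects["group_id"].value_counts()
    assert sizes.max() - sizes.min() <= 1
    assert subjects["age_years"].min() >= 1.0
    expected = np.where(subjects["age_years"] < 5, "juvenile", "adult")
    assert (subjects["age_group"] == expected).all()


def test_maternal_record_invariants(study_dataset):
    m = study_dataset.maternal
    assert (m["n_groom_scans"] <= m["n_scans"]).all()
    assert (m["n_cradle_scans"] <= m["n_scans"]).all()
    assert (m[["approach_count", "restrain_count"]] >= 0).all().all()
    # records exist exactly for the subjects carrying a mother_id
    with_mother = set(
        study_dataset.subjects.loc[study_dataset.subjects["mother_id"] != "",
                                   "subject_id"])
    assert set(m["subject_id"]) == with_mother


def test_determinism_same_seed():
    cfg = SimulationConfig(seed=123, n_subjects=20, n_groups=4)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    for name in ("subjects", "maternal", "skills", "trials_exp1",
                 "trials_exp2", "trials_exp3"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_different_seed_differs():
    a = generate_dataset(SimulationConfig(seed=1, n_subjects=20, n_groups=4))
    b = generate_dataset(SimulationConfig(seed=2, n_subjects=20, n_groups=4))
    assert not a.trials_exp1["look_expression_s"].equals(
        b.trials_exp1["look_expression_s"])


@pytest.mark.parametrize("field, value", [
    ("n_groups", 50), ("prob_female", 1.5), ("sd_resid", -1.0),
    ("dropout_rate", -0.1), ("age_range", (0.2, 10.0)),
])
def test_invalid_config_rejected(field, value):
    kwargs = {"seed": 0, "n_subjects": 10, "n_groups": 3, field: value}
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        SimulationConfig(**kwargs)


def test_null_model_skill_uncorrelated_with_grooming():
    """With all effects and random-effect SDs zero, skill is pure noise:
    its sample correlation with the grooming score is ~0 (Monte Carlo)."""
    cfg = SimulationConfig(
        seed=9, n_subjects=10000, n_groups=15,
        beta_groom=0, beta_cradle=0, beta_approach=0, beta_restrain=0,
        sd_group=0, sd_mother=0,
        age_curve=AgeCurve(juvenile_slope=0.0),
    )
    subjects, maternal, skills = generate_cohort(cfg)
    d = maternal.merge(skills, on="subject_id")
    groom = 100 * d["n_groom_scans"] / d["n_scans"]
    assert abs(np.corrcoef(groom, d["skill"])[0, 1]) < 0.03


def test_null_skill_distribution():
    """Under zero effects and zero RE variance, skill ~ N(0, sd_resid^2)."""
    cfg = SimulationConfig(
        seed=4, n_subjects=20000, n_groups=10, beta_groom=0, beta_cradle=0,
        beta_approach=0, beta_restrain=0, sd_group=0, sd_mother=0,
        sd_resid=0.4, age_curve=AgeCurve(juvenile_slope=0.0),
    )
    _, _, skills = generate_cohort(cfg)
    assert abs(skills["skill"].mean()) < 0.01
    assert abs(skills["skill"].std() - 0.4) < 0.01


def test_exp1_mean_proportion_recovers_configured_bias():
    """Scream-trial looking proportions average to 0.5 + the configured
    (negative) bias; the other expressions follow their own effects."""
    cfg = SimulationConfig(seed=11, n_subjects=2000, n_groups=15)
    subjects, _, skills = generate_cohort(cfg)
    t = generate_exp1_trials(subjects, skills, cfg)
    t = t[t["includable"]]
    p = t["look_expression_s"] / (t["look_expression_s"] + t["look_neutral_s"])
    by = p.groupby(t["expression"]).mean()
    assert by["scream"] == pytest.approx(0.43, abs=0.015)
    assert by["bared_teeth"] == pytest.approx(0.55, abs=0.015)
    assert by["threat"] == pytest.approx(0.51, abs=0.015)


def test_exp1_null_proportion_half():
    cfg = SimulationConfig(seed=12, n_subjects=2000, n_groups=15,
                           effect_scream_bias=0, effect_bt_bias=0,
                           effect_threat_bias=0, sd_bias_subject=0)
    subjects, _, skills = generate_cohort(cfg)
    t = generate_exp1_trials(subjects, skills, cfg)
    t = t[t["includable"]]
    p = t["look_expression_s"] / (t["look_expression_s"] + t["look_neutral_s"])
    assert p.mean() == pytest.approx(0.5, abs=0.01)


def test_full_dropout_leaves_no_includable_trials():
    cfg = SimulationConfig(seed=13, n_subjects=30, n_groups=5, dropout_rate=1.0)
    ds = generate_dataset(cfg)
    assert not ds.trials_exp1["includable"].any()
    assert not ds.trials_exp2["includable"].any()
    assert not ds.trials_exp3["includable"].any()


def test_exp2_intensities_in_design_set(study_dataset):
    assert set(study_dataset.trials_exp2["intensity"]).issubset(set(INTENSITIES))


def test_exp3_exact_trend_extrapolates_exactly():
    """With zero noise and zero excess, the sixth image continues the
    subject's linear trend exactly (when clipping is not engaged)."""
    cfg = SimulationConfig(seed=14, n_subjects=50, n_groups=5,
                           effect_violation_excess=0.0, sd_look_exp3=0.0,
                           missing_image_rate=0.0, dropout_rate=0.0)
    subjects, _, skills = generate_cohort(cfg)
    t = generate_exp3_trials(subjects, skills, cfg)
    looks = t[[f"look{i}_s" for i in range(1, 7)]].to_numpy()
    interior = ((looks > 0.05 + 1e-9) & (looks < 3.0 - 1e-9)).all(axis=1)
    x = np.arange(1, 6)
    for row in looks[interior]:
        slope, icept = np.polyfit(x, row[:5], 1)
        assert row[5] == pytest.approx(icept + slope * 6, abs=1e-8)


def test_exp3_missing_image_fraction():
    cfg = SimulationConfig(seed=15, n_subjects=1500, n_groups=15,
                           trials_exp3=2, missing_image_rate=0.3,
                           dropout_rate=0.0)
    subjects, _, skills = generate_cohort(cfg)
    t = generate_exp3_trials(subjects, skills, cfg)
    n_initial = t[[f"look{i}_s" for i in range(1, 6)]].notna().sum(axis=1)
    frac = (n_initial == 4).mean()
    # binomial check: 30% of trials have exactly one missing initial look
    assert frac == pytest.approx(0.3, abs=0.025)
    assert t["includable"].all()


def test_exp3_expression_constraints(study_dataset):
    t = study_dataset.trials_exp3
    assert set(t["sequence_expression"]) <= {"threat", "scream", "neutral"}
    assert set(t["violating_expression"]) <= {"threat", "scream", "bared_teeth"}
    assert (t["sequence_expression"] != t["violating_expression"]).all()


def test_write_read_round_trip(tmp_path, small_dataset):
    write_synthetic_dataset(small_dataset, tmp_path)
    back = read_synthetic_dataset(tmp_path)
    for name in ("subjects", "maternal", "skills", "trials_exp1",
                 "trials_exp2", "trials_exp3"):
        pd.testing.assert_frame_equal(
            getattr(small_dataset, name).reset_index(drop=True),
            getattr(back, name), check_dtype=False, atol=1e-12)
    assert back.config == small_dataset.config


def test_write_empty_dataset_has_headers(tmp_path):
    cfg = SimulationConfig(seed=1, n_subjects=2, n_groups=1, trials_exp1=0,
                           trials_exp2=0, trials_exp3=0)
    ds = generate_dataset(cfg)
    paths = write_synthetic_dataset(ds, tmp_path)
    for key in ("trials_exp1", "trials_exp2", "trials_exp3"):
        df = pd.read_csv(paths[key])
        assert len(df) == 0 and len(df.columns) > 3


def test_written_trial_counts_match_generated(tmp_path, study_dataset):
    paths = write_synthetic_dataset(study_dataset, tmp_path)
    for key, gen in (("trials_exp1", study_dataset.trials_exp1),
                     ("trials_exp2", study_dataset.trials_exp2),
                     ("trials_exp3", study_dataset.trials_exp3)):
        assert len(pd.read_csv(paths[key])) == len(gen)
    manifest = pd.read_csv(paths["manifest"])
    counts = manifest["experiment"].value_counts()
    assert counts["exp1"] == len(study_dataset.trials_exp1)
    assert counts["exp2"] == len(study_dataset.trials_exp2)
    assert counts["exp3"] == len(study_dataset.trials_exp3)
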