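"""Event ingestion, trial assembly, inclusion filters, and ICC."""

import numpy as np
import pandas as pd
import pytest

from facebias import (
    DegenerateInputError, SchemaError, ValidationError, assemble_trials,
    apply_inclusion_filters, compute_icc, read_event_table,
    write_synthetic_dataset,
)
from conftest import exp3_manifest_row, make_event_rows, paired_manifest_row


# -- read_event_table -------------------------------------------------------

def test_read_well_formed_events(tmp_path):
    p = tmp_path / "e.csv"
    make_event_rows("T1", [("left", 0.0, 1.5), ("right", 1.5, 2.0),
                           ("screen", 2.0, 2.4)]).to_csv(p, index=False)
    ev = read_event_table(p)
    assert len(ev) == 3
    # frame-export shorthand targets are normalized
    assert set(ev["target"]) == {"left_screen", "right_screen", "screen"}


def test_read_rejects_stop_before_start(tmp_path):
    p = tmp_path / "e.csv"
    make_event_rows("T1", [("left", 1.0, 0.5)]).to_csv(p, index=False)
    with pytest.raises(ValidationError, match="row 2"):
        read_event_table(p)


def test_read_rejects_missing_column(tmp_path):
    p = tmp_path / "e.csv"
    make_event_rows("T1", [("left", 0.0, 1.0)]).drop(
        columns="stop_s").to_csv(p, index=False)
    with pytest.raises(SchemaError, match="stop_s"):
        read_event_table(p)


def test_read_rejects_overlapping_stream(tmp_path):
    p = tmp_path / "e.csv"
    make_event_rows("T1", [("left", 0.0, 2.0), ("left", 1.0, 3.0)]).to_csv(
        p, index=False)
    with pytest.raises(ValidationError, match="overlap"):
        read_event_table(p)


def test_synthetic_events_parse_losslessly(tmp_path, small_dataset):
    paths = write_synthetic_dataset(small_dataset, tmp_path)
    ev = read_event_table(paths["events"])
    raw = pd.read_csv(paths["events"])
    assert len(ev) == len(raw)
    assert np.allclose(ev["stop_s"] - ev["start_s"],
                       raw["stop_s"] - raw["start_s"])


# -- assemble_trials --------------------------------------------------------

def test_side_swap_bookkeeping():
    """Expression left in window 1 (2.0 s looked left), right in window 2
    (1.2 s looked right) sums to 3.2 s at the expression."""
    ev = make_event_rows("T1", [("left_screen", 0.0, 2.0),
                                ("right_screen", 6.0, 7.2),
                                ("left_screen", 7.2, 8.0)])
    mf = pd.DataFrame([paired_manifest_row("T1", expr_side="left")])
    out = assemble_trials(ev, mf)["exp1"]
    assert out.loc[0, "look_expression_s"] == pytest.approx(3.2)
    assert out.loc[0, "look_neutral_s"] == pytest.approx(0.8)
    assert out.loc[0, "includable"]


def test_no_events_means_zero_durations_not_includable():
    ev = make_event_rows("T1", [("left_screen", 0.0, 1.0)])
    mf = pd.DataFrame([paired_manifest_row("T1"),
                       paired_manifest_row("T2", subject_id="S2")])
    out = assemble_trials(ev, mf)["exp1"]
    t2 = out[out["trial_id"] == "T2"].iloc[0]
    assert t2["look_expression_s"] == 0 and t2["look_neutral_s"] == 0
    assert not t2["includable"]


def test_event_straddling_gap_truncated_at_window_edges():
    # 4.0 -> 6.0 spans the 0.5 s black screen; only 1.0 + 0.5 s count
    ev = make_event_rows("T1", [("left_screen", 4.0, 6.0)])
    mf = pd.DataFrame([paired_manifest_row("T1", expr_side="left")])
    out = assemble_trials(ev, mf)["exp1"]
    # window 1 contributes [4,5] at expression side; window 2 has the
    # expression on the right, so [5.5,6] looking left is neutral time
    assert out.loc[0, "look_expression_s"] == pytest.approx(1.0)
    assert out.loc[0, "look_neutral_s"] == pytest.approx(0.5)


def test_exp3_assembly_and_five_image_inclusion():
    specs = [("screen", o, o + 1.0) for o in (0.0, 3.5, 7.0, 14.0, 17.5)]
    ev = make_event_rows("T1", specs)
    mf = pd.DataFrame([exp3_manifest_row("T1")])
    out = assemble_trials(ev, mf)["exp3"]
    row = out.iloc[0]
    assert row[["look1_s", "look2_s", "look3_s", "look5_s", "look6_s"]].notna().all()
    assert pd.isna(row["look4_s"])
    assert row["includable"]  # 4 of 5 initial + final image seen


def test_unknown_trial_in_events_raises():
    ev = make_event_rows("GHOST", [("left_screen", 0.0, 1.0)])
    mf = pd.DataFrame([paired_manifest_row("T1")])
    with pytest.raises(ValidationError, match="GHOST"):
        assemble_trials(ev, mf)


def test_assembly_permutation_invariant(small_dataset, tmp_path):
    paths = write_synthetic_dataset(small_dataset, tmp_path)
    ev = read_event_table(paths["events"])
    mf = pd.read_csv(paths["manifest"])
    a = assemble_trials(ev, mf)
    b = assemble_trials(ev.sample(frac=1, random_state=0), mf)
    for exp in ("exp1", "exp2", "exp3"):
        pd.testing.assert_frame_equal(a[exp], b[exp])


def test_durations_bounded_by_stimulus_on_time(small_dataset, tmp_path):
    paths = write_synthetic_dataset(small_dataset, tmp_path)
    trials = assemble_trials(read_event_table(paths["events"]),
                             pd.read_csv(paths["manifest"]))
    for exp in ("exp1", "exp2"):
        total = trials[exp]["look_expression_s"] + trials[exp]["look_neutral_s"]
        assert (total <= 10.0 + 1e-9).all()
    look_cols = [f"look{i}_s" for i in range(1, 7)]
    assert (trials["exp3"][look_cols].sum(axis=1, skipna=True) <= 18.0 + 1e-9).all()


# -- apply_inclusion_filters ------------------------------------------------

def test_exp1_exclusion_reason_did_not_look_both():
    trials = pd.DataFrame([
        {"trial_id": "a", "subject_id": "S1", "look_expression_s": 2.0,
         "look_neutral_s": 0.0, "includable": False},
        {"trial_id": "b", "subject_id": "S1", "look_expression_s": 2.0,
         "look_neutral_s": 1.0, "includable": True},
    ])
    inc, exc = apply_inclusion_filters(trials, "exp1")
    assert list(inc["trial_id"]) == ["b"]
    assert list(exc["exclusion_reason"]) == ["did_not_look_both"]


@pytest.mark.parametrize("n_initial, included", [(3, False), (4, True), (5, True)])
def test_exp3_initial_look_rule(n_initial, included):
    looks = {f"look{i}_s": (1.0 if i <= n_initial else np.nan) for i in range(1, 6)}
    looks["look6_s"] = 1.0
    trials = pd.DataFrame([{"trial_id": "t", "subject_id": "S1",
                            "includable": True, **looks}])
    inc, exc = apply_inclusion_filters(trials, "exp3")
    assert (len(inc) == 1) is included
    if not included:
        assert exc.loc[0, "exclusion_reason"] == "too_few_initial_looks"


def test_all_includable_set_has_empty_exclusions(small_config):
    from facebias import generate_dataset

    ds = generate_dataset(small_config.replace(dropout_rate=0.0,
                                               missing_image_rate=0.0))
    for exp in ("exp1", "exp2", "exp3"):
        _, exc = apply_inclusion_filters(getattr(ds, f"trials_{exp}"), exp)
        assert len(exc) == 0


def test_dropout_fraction_excluded():
    """With dropout_rate d, the filtered-out fraction is d up to MC error."""
    from facebias import SimulationConfig, generate_dataset

    ds = generate_dataset(SimulationConfig(seed=21, n_subjects=1000,
                                           n_groups=15, dropout_rate=0.30))
    for exp in ("exp1", "exp2", "exp3"):
        trials = getattr(ds, f"trials_{exp}")
        _, exc = apply_inclusion_filters(trials, exp)
        assert len(exc) / len(trials) == pytest.approx(0.30, abs=0.03)


# -- compute_icc ------------------------------------------------------------

def _codings(values_by_coder):
    rows = []
    for coder, vals in values_by_coder.items():
        rows += [{"trial_id": f"u{i}", "coder_id": coder, "duration_s": v}
                 for i, v in enumerate(vals)]
    return pd.DataFrame(rows)


def test_icc_perfect_agreement_is_one():
    vals = [4.0, 2.0, 6.0, 3.0, 5.0]
    icc = compute_icc(_codings({"C1": vals, "C2": vals}))
    assert icc.estimate == pytest.approx(1.0, abs=1e-9)
    assert icc.p_value < 0.001


def test_icc_near_zero_when_noise_swamps_units():
    """Coder 2 adds noise with variance far above the between-unit
    variance, so agreement is essentially nil (variance-component oracle:
    ICC ~ sigma_b^2 / (sigma_b^2 + sigma_e^2) -> 0)."""
    rng = np.random.default_rng(3)
    base = rng.normal(5.0, 0.05, 40)
    icc = compute_icc(_codings({"C1": base,
                                "C2": base + rng.normal(0, 5.0, 40)}))
    assert abs(icc.estimate) < 0.35


def test_icc_matches_anova_mean_squares_oracle():
    """ICC(2,k) from pingouin equals the classical two-way ANOVA
    mean-squares formula computed by hand."""
    rng = np.random.default_rng(11)
    n, k = 12, 2
    base = rng.normal(6, 1.5, n)
    data = np.column_stack([base + rng.normal(0, 0.6, n) for _ in range(k)])
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = ((data - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True) + grand) ** 2).sum() / ((n - 1) * (k - 1))
    icc2k_oracle = (msr - mse) / (msr + (msc - mse) / n)
    icc = compute_icc(_codings({"C1": data[:, 0], "C2": data[:, 1]}))
    assert icc.estimate == pytest.approx(icc2k_oracle, abs=1e-9)


@pytest.mark.parametrize("bad", [
    _codings({"C1": [1.0, 2.0, 3.0, 4.0, 5.0]}),                 # one coder
    _codings({"C1": [1.0] * 5, "C2": [1.0] * 5}),                # constant
    _codings({"C1": [1.0, 2.0], "C2": [1.0, 2.0]}),              # too few units
])
def test_icc_degenerate_inputs_raise(bad):
    with pytest.raises(DegenerateInputError):
        compute_icc(bad)
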