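"""Ingestion of coded looking-event exports.

Behavioral-observation software exports gaze-direction codes as
interval events (frame-by-frame codes collapsed to start/stop
intervals). This module reads such event tables, assembles per-trial
looking times using a trial manifest that carries the stimulus timing
and side assignment, applies the study's inclusion criteria, and
computes inter-coder reliability.

Inclusion criteria: for the paired-presentation experiments the
subject must have looked at both the expression and the neutral image;
for the sequence experiment it must have looked at at least four of
the five initial images and at the final image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError, ValidationError
from .results import ICCResult

__all__ = [
    "read_event_table",
    "assemble_trials",
    "apply_inclusion_filters",
    "compute_icc",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["trial_id", "coder_id", "target", "start_s", "stop_s"]
VALID_TARGETS = {"left_screen", "right_screen", "screen", "away",
                 "left", "right"}

EXCLUDE_DID_NOT_LOOK_BOTH = "did_not_look_both"
EXCLUDE_TOO_FEW_INITIAL = "too_few_initial_looks"
EXCLUDE_NO_FINAL_LOOK = "no_final_look"


def read_event_table(path) -> pd.DataFrame:
    """Read and validate a coded looking-event CSV.

    Columns: trial_id, coder_id, target, start_s, stop_s. Raises
    :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming row numbers) for malformed rows.
    """
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table {path} is missing column(s): {missing}")
    events = events[EVENT_COLUMNS].copy()
    problems = []
    for col in ("start_s", "stop_s"):
        bad = pd.to_numeric(events[col], errors="coerce").isna() & events[col].notna()
        for i in events.index[bad]:
            problems.append(f"row {i + 2}: non-numeric {col}")
        events[col] = pd.to_numeric(events[col], errors="coerce")
    nonpos = events["stop_s"] <= events["start_s"]
    for i in events.index[nonpos.fillna(True)]:
        problems.append(f"row {i + 2}: stop_s must be greater than start_s")
    bad_target = ~events["target"].isin(VALID_TARGETS)
    for i in events.index[bad_target]:
        problems.append(f"row {i + 2}: unknown target {events.loc[i, 'target']!r}")
    if problems:
        raise ValidationError(
            "invalid event rows:\n  " + "\n  ".join(problems[:20]))
    events["target"] = events["target"].replace(
        {"left": "left_screen", "right": "right_screen"})
    # events within one (trial, coder, target) stream must not overlap
    for (tid, cid, tgt), grp in events.groupby(["trial_id", "coder_id", "target"]):
        g = grp.sort_values("start_s")
        if (g["start_s"].to_numpy()[1:] < g["stop_s"].to_numpy()[:-1] - 1e-9).any():
            raise ValidationError(
                f"overlapping events for trial {tid!r}, coder {cid!r}, "
                f"target {tgt!r}")
    return events


def _overlap(start, stop, w_start, w_stop):
    """Seconds of [start, stop) overlapping [w_start, w_stop); events
    straddling a window edge are truncated at the edge."""
    return np.maximum(0.0, np.minimum(stop, w_stop) - np.maximum(start, w_start))


def assemble_trials(events: pd.DataFrame, manifest: pd.DataFrame,
                    coder_id: "str | None" = None) -> dict:
    """Assemble per-trial looking times from events and a trial manifest.

    The manifest carries the stimulus timing (presentation windows and,
    for the paired experiments, which side the expression occupied in
    window 1; sides swap between windows). Returns a dict with keys
    ``exp1``, ``exp2``, ``exp3`` of per-experiment trial tables.
    Events referencing trials absent from the manifest raise
    :class:`ValidationError`; events falling outside every stimulus
    window are logged and dropped.
    """
    required = {"trial_id", "subject_id", "experiment"}
    missing = required - set(manifest.columns)
    if missing:
        raise SchemaError(f"manifest is missing column(s): {sorted(missing)}")
    known = set(manifest["trial_id"])
    unknown = set(events["trial_id"]) - known
    if unknown:
        raise ValidationError(
            f"events reference trial(s) not in manifest: {sorted(unknown)[:5]}")
    if coder_id is not None:
        events = events[events["coder_id"] == coder_id]

    by_trial = {tid: grp for tid, grp in events.groupby("trial_id")}
    empty = pd.DataFrame(columns=EVENT_COLUMNS)
    out1, out2, out3 = [], [], []
    n_outside = 0

    for _, t in manifest.iterrows():
        ev = by_trial.get(t["trial_id"], empty)
        starts = ev["start_s"].to_numpy(float) if len(ev) else np.empty(0)
        stops = ev["stop_s"].to_numpy(float) if len(ev) else np.empty(0)
        targets = ev["target"].to_numpy() if len(ev) else np.empty(0, object)

        if t["experiment"] in ("exp1", "exp2"):
            windows = [(float(t["win1_start"]), float(t["win1_start"]) + float(t["win1_dur"])),
                       (float(t["win2_start"]), float(t["win2_start"]) + float(t["win2_dur"]))]
            s1 = t["expr_side_win1"]
            expr_sides = [s1, "right" if s1 == "left" else "left"]
            look_e = look_n = 0.0
            covered = np.zeros(len(starts))
            for (ws, we), eside in zip(windows, expr_sides):
                ov = _overlap(starts, stops, ws, we)
                covered += ov
                eside_t = f"{eside}_screen"
                is_expr = targets == eside_t
                is_neut = np.isin(targets, ["left_screen", "right_screen"]) & ~is_expr
                look_e += float(ov[is_expr].sum())
                look_n += float(ov[is_neut].sum())
            n_outside += int(((stops - starts) - covered > 1e-9).sum())
            row = {
                "trial_id": t["trial_id"], "subject_id": t["subject_id"],
                "group_id": t.get("group_id", ""),
                "expression": t["expression"],
                "look_expression_s": look_e, "look_neutral_s": look_n,
                "includable": bool(look_e > 0 and look_n > 0),
            }
            if t["experiment"] == "exp1":
                out1.append(row)
            else:
                row["intensity"] = float(t["intensity"])
                out2.append(row)
        elif t["experiment"] == "exp3":
            onsets = [float(x) for x in str(t["image_onsets"]).split(";")]
            dur = float(t["image_dur"])
            looks = []
            covered = np.zeros(len(starts))
            for onset in onsets:
                ov = _overlap(starts, stops, onset, onset + dur)
                ov = np.where(targets == "screen", ov, 0.0)
                covered += ov
                tot = float(ov.sum())
                looks.append(tot if tot > 0 else np.nan)
            n_outside += int(((stops - starts) - covered > 1e-9).sum())
            n_initial = int(np.sum(~np.isnan(looks[:5])))
            row = {
                "trial_id": t["trial_id"], "subject_id": t["subject_id"],
                "group_id": t.get("group_id", ""),
                "sequence_expression": t["sequence_expression"],
                "violating_expression": t["violating_expression"],
                "includable": bool(n_initial >= 4 and not np.isnan(looks[5])),
            }
            row.update({f"look{i + 1}_s": looks[i] for i in range(6)})
            out3.append(row)
        else:
            raise ValidationError(
                f"unknown experiment {t['experiment']!r} for trial {t['trial_id']!r}")

    if n_outside:
        logger.warning("%d event(s) extended outside all stimulus windows; "
                       "out-of-window time dropped", n_outside)

    cols3 = ["trial_id", "subject_id", "group_id", "sequence_expression",
             "violating_expression"] + [f"look{i}_s" for i in range(1, 7)] + ["includable"]
    return {
        "exp1": pd.DataFrame(out1, columns=["trial_id", "subject_id", "group_id",
                                            "expression", "look_expression_s",
                                            "look_neutral_s", "includable"]),
        "exp2": pd.DataFrame(out2, columns=["trial_id", "subject_id", "group_id",
                                            "expression", "intensity",
                                            "look_expression_s", "look_neutral_s",
                                            "includable"]),
        "exp3": pd.DataFrame(out3, columns=cols3),
    }


def apply_inclusion_filters(trials: pd.DataFrame, experiment: str):
    """Partition assembled trials into (included, excluded-with-reasons).

    Exclusion reasons are machine-readable: ``did_not_look_both`` for
    the paired experiments; ``too_few_initial_looks`` /
    ``no_final_look`` for the sequence experiment.
    """
    trials = trials.copy()
    if experiment in ("exp1", "exp2"):
        ok = (trials["look_expression_s"] > 0) & (trials["look_neutral_s"] > 0)
        reason = np.where(ok, "", EXCLUDE_DID_NOT_LOOK_BOTH)
    elif experiment == "exp3":
        look_cols = [f"look{i}_s" for i in range(1, 6)]
        n_initial = trials[look_cols].notna().sum(axis=1)
        final_ok = trials["look6_s"].notna()
        ok = (n_initial >= 4) & final_ok
        reason = np.where(~final_ok, EXCLUDE_NO_FINAL_LOOK,
                          np.where(n_initial < 4, EXCLUDE_TOO_FEW_INITIAL, ""))
    else:
        raise ValidationError(f"unknown experiment {experiment!r}")
    included = trials[ok].reset_index(drop=True)
    excluded = trials[~ok].reset_index(drop=True)
    excluded["exclusion_reason"] = reason[~np.asarray(ok)]
    logger.info("%s: %d trial(s) excluded of %d", experiment, len(excluded),
                len(trials))
    return included, excluded


def compute_icc(paired_codings: pd.DataFrame, form: str = "ICC2k",
                min_units: int = 5) -> ICCResult:
    """Inter-coder reliability of duration measurements.

    ``paired_codings`` is long-format with columns trial_id, coder_id,
    duration_s (every coder must rate every unit). The default form is
    the two-way random-effects, absolute-agreement, average-measures
    ICC (ICC2k) — the reliability of the mean of the coders' measures;
    other pingouin forms (e.g. ``ICC3k``) can be requested.
    """
    import pingouin as pg

    required = {"trial_id", "coder_id", "duration_s"}
    missing = required - set(paired_codings.columns)
    if missing:
        raise SchemaError(f"paired codings missing column(s): {sorted(missing)}")
    wide = paired_codings.pivot(index="trial_id", columns="coder_id",
                                values="duration_s").dropna()
    n_units, n_raters = wide.shape
    if n_raters < 2:
        raise DegenerateInputError("at least two coders are required")
    if n_units < min_units:
        raise DegenerateInputError(
            f"at least {min_units} double-coded units are required (got {n_units})")
    values = wide.to_numpy(float)
    if np.allclose(values, values.ravel()[0]):
        raise DegenerateInputError("constant ratings: ICC is undefined")

    long = wide.reset_index().melt(id_vars="trial_id", var_name="coder_id",
                                   value_name="duration_s")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(data=long, targets="trial_id",
                                 raters="coder_id", ratings="duration_s")
    # short names map onto pingouin's Shrout-Fleiss labels
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
               "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}
    table = icc.set_index("Type")
    row = table.loc[aliases.get(form, form)]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = (float(x) for x in row[ci_col])
    pval = float(row["pval"])
    if not np.isfinite(pval):  # perfect agreement: F statistic is infinite
        pval = 0.0
    return ICCResult(
        estimate=float(row["ICC"]), ci_low=ci_low, ci_high=ci_high,
        p_value=pval, form=form, n_units=n_units, n_raters=n_raters,
    )
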