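"""Synthetic study datasets with known ground truth.

Generates a macaque cohort (subjects, maternal-care records, latent
facial-expression-processing skill) and trial-level looking times for
the three experiments:

* Experiment 1 — paired presentation of an expression (bared-teeth,
  threat, or scream) against a neutral face, two 5-s windows with the
  expression swapping sides;
* Experiment 2 — threat-avatar intensities (25/50/75/100%) against
  neutral, same paired design;
* Experiment 3 — five 3-s same-expression images followed by a
  sequence-violating expression.

Latent skill is a linear function of maternal care (grooming, cradling,
approaching, restraining), an age curve (rising to age 5, flat after),
group and mother random intercepts, and residual noise. Skill enters
trial behavior through a positive multiplicative factor
``m_i = exp(lambda * skill_i)`` normalized to cohort mean 1, so the
configured effect sizes equal cohort-average effects and parameter
recovery has a well-defined truth.

Per-trial looking proportions are truncated-normal around the condition
mean; total looking time per paired trial is truncated-normal and split
by the proportion, so the written looking *times* are positive and
bounded by the stimulus-on time while the proportion keeps the
configured expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .exceptions import ConfigurationError

__all__ = [
    "SyntheticDataset",
    "generate_cohort",
    "generate_exp1_trials",
    "generate_exp2_trials",
    "generate_exp3_trials",
    "generate_dataset",
    "simulate_double_coding",
    "write_synthetic_dataset",
    "read_synthetic_dataset",
]

EXPRESSIONS = ("bared_teeth", "threat", "scream")
INTENSITIES = (0.25, 0.50, 0.75, 1.00)
SEQUENCE_EXPRESSIONS = ("threat", "scream", "neutral")
VIOLATING_EXPRESSIONS = ("threat", "scream", "bared_teeth")

# stimulus timing carried into the trial manifest
EXP12_WINDOWS = ((0.0, 5.0), (5.5, 5.0))  # (start, duration): 5 s, 0.5 s gap, 5 s
EXP3_IMAGE_DUR = 3.0
EXP3_GAP = 0.5


@dataclass
class SyntheticDataset:
    """A complete synthetic study: cohort tables plus per-experiment trials."""

    config: SimulationConfig
    subjects: pd.DataFrame
    maternal: pd.DataFrame
    skills: pd.DataFrame
    trials_exp1: pd.DataFrame
    trials_exp2: pd.DataFrame
    trials_exp3: pd.DataFrame


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic sub-stream per module
    return np.random.default_rng([int(config.seed), stream])


def _truncnorm(rng, mean, sd, lo, hi):
    mean = np.asarray(mean, float)
    if np.isscalar(sd):
        sd = np.full(mean.shape, float(sd))
    sd = np.maximum(np.asarray(sd, float), 1e-12)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig):
    """Generate subjects, maternal-care records, and latent skills.

    Returns ``(subjects, maternal, skills)`` DataFrames. All subjects
    have a (latent) mother and maternal behavior; records are exported
    in ``maternal`` only for the ``prob_maternal_data`` fraction,
    mirroring a cohort where historical husbandry data exist for a
    subset. ``skills`` carries the ground-truth latent skill.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigurationError("config must be a SimulationConfig")
    rng = _rng(config, 11)
    n = config.n_subjects

    subject_id = np.array([f"S{i + 1:03d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.prob_female, "female", "male")
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)

    # round-robin-with-jitter group assignment: shuffle, then deal cyclically
    order = rng.permutation(n)
    group_idx = np.empty(n, int)
    group_idx[order] = np.arange(n) % config.n_groups
    group_id = np.array([f"G{g + 1:02d}" for g in group_idx])

    # mothers drawn from a per-group pool of about half the group size,
    # so siblings are common (breeding females produce offspring across
    # years) and the mother variance component is identifiable
    mother_id = np.empty(n, object)
    for g in range(config.n_groups):
        members = np.flatnonzero(group_idx == g)
        pool = max(1, int(round(0.5 * len(members)))) if len(members) else 1
        picks = rng.integers(0, pool, len(members))
        for i, k in zip(members, picks):
            mother_id[i] = f"M{g + 1:02d}_{k + 1}"

    has_maternal = rng.random(n) < config.prob_maternal_data

    # maternal behavior (latent for everyone; recorded for the subset)
    n_scans = config.n_focals * config.scans_per_focal
    ga, gb = config.groom_beta_params
    ca, cb = config.cradle_beta_params
    p_groom = rng.beta(ga, gb, n)
    p_cradle = rng.beta(ca, cb, n)
    n_groom = rng.binomial(n_scans, p_groom)
    n_cradle = rng.binomial(n_scans, p_cradle)
    approach_count = rng.poisson(config.n_focals * config.approach_rate_mean, n)
    restrain_count = rng.poisson(config.n_focals * config.restrain_rate_mean, n)

    grooming_pct = 100.0 * n_groom / n_scans
    cradling_pct = 100.0 * n_cradle / n_scans
    approach_rate = approach_count / config.n_focals
    restrain_rate = restrain_count / config.n_focals

    # latent skill: centered linear predictor + random effects + noise
    groom_c = 100.0 * ga / (ga + gb)
    cradle_c = 100.0 * ca / (ca + cb)
    age_c = config.age_curve.mean_uniform(lo, hi)
    u_group = rng.normal(0.0, config.sd_group, config.n_groups)[group_idx]
    mothers, mother_inv = np.unique(mother_id.astype(str), return_inverse=True)
    u_mother = rng.normal(0.0, config.sd_mother, len(mothers))[mother_inv]
    eps = rng.normal(0.0, config.sd_resid, n)
    skill = (
        config.beta_groom * (grooming_pct - groom_c)
        + config.beta_cradle * (cradling_pct - cradle_c)
        + config.beta_approach * (approach_rate - config.approach_rate_mean)
        + config.beta_restrain * (restrain_rate - config.restrain_rate_mean)
        + (config.age_curve.value(age) - age_c)
        + u_group
        + u_mother
        + eps
    )

    subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": sex,
            "age_years": age,
            "group_id": group_id,
            "mother_id": np.where(has_maternal, mother_id.astype(str), ""),
            "age_group": np.where(age < 5.0, "juvenile", "adult"),
        }
    )
    maternal = pd.DataFrame(
        {
            "subject_id": subject_id,
            "n_scans": n_scans,
            "n_groom_scans": n_groom,
            "n_cradle_scans": n_cradle,
            "approach_count": approach_count,
            "restrain_count": restrain_count,
            "n_focals": config.n_focals,
        }
    )[has_maternal].reset_index(drop=True)
    skills = pd.DataFrame({"subject_id": subject_id, "skill": skill})
    return subjects, maternal, skills


def _skill_factor(skills: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Positive multiplicative skill link, normalized to cohort mean 1."""
    m = np.exp(config.skill_link_scale * skills["skill"].to_numpy(float))
    m = m / m.mean()
    return pd.Series(m, index=skills["subject_id"].to_numpy())


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _paired_trials(subjects, skills, config, rng, experiment, condition_effects):
    """Shared machinery for the two paired-presentation experiments.

    ``condition_effects[c]`` is the signed deviation of the expected
    looking proportion from 0.5 for condition ``c`` (before skill
    scaling). Fully vectorized: one truncated-normal draw per array.
    """
    n_trials = config.trials_exp1 if experiment == "exp1" else config.trials_exp2
    n_cond = len(condition_effects)
    n_subj = len(subjects)
    if n_subj == 0 or n_trials == 0:
        return pd.DataFrame(
            columns=["trial_id", "subject_id", "group_id", "condition",
                     "expr_side_win1", "look_expression_s", "look_neutral_s",
                     "includable"]
        )
    m = _skill_factor(skills, config).to_numpy()

    # cycle conditions in random order per subject so trial counts stay balanced
    reps = n_trials // n_cond + 1
    blocks = np.tile(np.arange(n_cond), (n_subj * reps, 1))
    blocks = rng.permuted(blocks, axis=1).reshape(n_subj, reps * n_cond)
    cond = blocks[:, :n_trials].ravel()

    subj_idx = np.repeat(np.arange(n_subj), n_trials)
    trial_no = np.tile(np.arange(1, n_trials + 1), n_subj)
    delta = np.asarray(condition_effects, float)[cond] * m[subj_idx]
    # stable idiosyncratic biases: direction subject-specific (per
    # condition for the expression experiment, per subject for the
    # intensity experiment), magnitude scaling with skill — this is the
    # individual variation the absolute-bias composite score measures
    if experiment == "exp1":
        wobble_base = rng.normal(0.0, 1.0, (n_subj, n_cond))
        wobble = wobble_base[subj_idx, cond]
    else:
        wobble = rng.normal(0.0, 1.0, n_subj)[subj_idx]
    offset = config.sd_bias_subject * m[subj_idx] * wobble
    if experiment == "exp2":
        # directional vigilance toward the threat avatar grows with skill
        offset = offset + config.effect_vigilance * (m[subj_idx] - 1.0)
    # individual offsets saturate well inside the proportion bounds, so
    # rare extreme subjects do not pile against the floor/ceiling and
    # attenuate the condition-effect estimands
    offset = 0.25 * np.tanh(offset / 0.25)
    p = _truncnorm(rng, 0.5 + delta + offset, config.sd_bias_trial, 0.02, 0.98)
    total = _truncnorm(rng, np.full(p.shape, config.total_look_mean),
                       config.total_look_sd, 0.5, 9.5)
    look_e = p * total
    look_n = (1.0 - p) * total

    dropped = rng.random(len(p)) < config.dropout_rate
    zero_expr = rng.random(len(p)) < 0.5
    # failed inclusion: never looked at one of the two images
    look_e = np.where(dropped & zero_expr, 0.0, look_e)
    look_n = np.where(dropped & ~zero_expr, 0.0, look_n)

    sid = subjects["subject_id"].to_numpy()
    return pd.DataFrame(
        {
            "trial_id": [f"{experiment.upper()}_{s}_T{t}"
                         for s, t in zip(sid[subj_idx], trial_no)],
            "subject_id": sid[subj_idx],
            "group_id": subjects["group_id"].to_numpy()[subj_idx],
            "condition": cond,
            "expr_side_win1": np.where(rng.random(len(p)) < 0.5, "left", "right"),
            "look_expression_s": look_e,
            "look_neutral_s": look_n,
            "includable": ~dropped,
        }
    )


def generate_exp1_trials(subjects, skills, config: SimulationConfig) -> pd.DataFrame:
    """Experiment 1: expression vs neutral paired-presentation trials."""
    rng = _rng(config, 21)
    effects = [config.effect_bt_bias, config.effect_threat_bias,
               config.effect_scream_bias]
    df = _paired_trials(subjects, skills, config, rng, "exp1", effects)
    if df.empty:
        return pd.DataFrame(
            columns=["trial_id", "subject_id", "group_id", "expression",
                     "stimulus_pair_id", "expr_side_win1",
                     "look_expression_s", "look_neutral_s", "includable"]
        )
    df["expression"] = df.pop("condition").map(dict(enumerate(EXPRESSIONS)))
    df["stimulus_pair_id"] = [
        f"{e}_p{k}" for e, k in zip(df["expression"], rng.integers(1, 4, len(df)))
    ]
    cols = ["trial_id", "subject_id", "group_id", "expression", "stimulus_pair_id",
            "expr_side_win1", "look_expression_s", "look_neutral_s", "includable"]
    return df[cols]


def generate_exp2_trials(subjects, skills, config: SimulationConfig) -> pd.DataFrame:
    """Experiment 2: threat intensity vs neutral paired-presentation trials."""
    rng = _rng(config, 22)
    effects = [config.effect_intensity_slope * (x - config.intensity_center)
               for x in INTENSITIES]
    df = _paired_trials(subjects, skills, config, rng, "exp2", effects)
    if df.empty:
        return pd.DataFrame(
            columns=["trial_id", "subject_id", "group_id", "expression", "intensity",
                     "expr_side_win1", "look_expression_s", "look_neutral_s",
                     "includable"]
        )
    df["intensity"] = df.pop("condition").map(dict(enumerate(INTENSITIES)))
    df["expression"] = "threat"
    cols = ["trial_id", "subject_id", "group_id", "expression", "intensity",
            "expr_side_win1", "look_expression_s", "look_neutral_s", "includable"]
    return df[cols]


def generate_exp3_trials(subjects, skills, config: SimulationConfig) -> pd.DataFrame:
    """Experiment 3: expectation-violation sequences.

    Looking times at images 1-5 follow a subject-trial linear decline
    plus noise; the sixth image adds the configured violation excess
    (scaled by skill) to the trend's extrapolation.
    """
    rng = _rng(config, 23)
    cols = ["trial_id", "subject_id", "group_id", "sequence_expression",
            "violating_expression"] + [f"look{i}_s" for i in range(1, 7)] + ["includable"]
    n_subj = len(subjects)
    n_trials = config.trials_exp3
    if n_subj == 0 or n_trials == 0:
        return pd.DataFrame(columns=cols)
    m = _skill_factor(skills, config).to_numpy()

    N = n_subj * n_trials
    subj_idx = np.repeat(np.arange(n_subj), n_trials)
    trial_no = np.tile(np.arange(1, n_trials + 1), n_subj)

    b0 = _truncnorm(rng, np.full(N, config.exp3_base_mean), config.exp3_base_sd,
                    0.8, 2.8)
    trend = rng.normal(config.exp3_trend_mean, config.exp3_trend_sd, N)
    means = b0[:, None] + trend[:, None] * np.arange(6)[None, :]
    means[:, 5] += config.effect_violation_excess * m[subj_idx]
    if config.sd_look_exp3 > 0:
        looks = _truncnorm(rng, means, config.sd_look_exp3, 0.05, EXP3_IMAGE_DUR)
    else:
        looks = np.clip(means, 0.05, EXP3_IMAGE_DUR)
    looks = np.asarray(looks, float).reshape(N, 6)

    # a fraction of trials misses exactly one of the first five images
    missing = rng.random(N) < config.missing_image_rate
    miss_pos = rng.integers(0, 5, N)
    looks[np.flatnonzero(missing), miss_pos[missing]] = np.nan

    # dropouts fail the inclusion rule: either the final image was never
    # looked at, or fewer than four of the first five were
    dropped = rng.random(N) < config.dropout_rate
    drop_final = rng.random(N) < 0.5
    looks[dropped & drop_final, 5] = np.nan
    for i in np.flatnonzero(dropped & ~drop_final):
        present = np.flatnonzero(~np.isnan(looks[i, :5]))
        kill = rng.choice(present, size=len(present) - 3, replace=False)
        looks[i, kill] = np.nan

    seq_idx = rng.integers(0, len(SEQUENCE_EXPRESSIONS), N)
    seq = np.array(SEQUENCE_EXPRESSIONS)[seq_idx]
    viol = np.empty(N, object)
    for i in range(N):
        opts = [v for v in VIOLATING_EXPRESSIONS if v != seq[i]]
        viol[i] = opts[rng.integers(0, len(opts))]

    sid = subjects["subject_id"].to_numpy()
    df = pd.DataFrame(
        {
            "trial_id": [f"EXP3_{s}_T{t}" for s, t in zip(sid[subj_idx], trial_no)],
            "subject_id": sid[subj_idx],
            "group_id": subjects["group_id"].to_numpy()[subj_idx],
            "sequence_expression": seq,
            "violating_expression": viol.astype(str),
            "includable": ~dropped,
        }
    )
    for i in range(6):
        df[f"look{i + 1}_s"] = looks[:, i]
    return df[cols]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full study: cohort plus all three experiments."""
    subjects, maternal, skills = generate_cohort(config)
    return SyntheticDataset(
        config=config,
        subjects=subjects,
        maternal=maternal,
        skills=skills,
        trials_exp1=generate_exp1_trials(subjects, skills, config),
        trials_exp2=generate_exp2_trials(subjects, skills, config),
        trials_exp3=generate_exp3_trials(subjects, skills, config),
    )


def simulate_double_coding(dataset: SyntheticDataset, n_videos: int = 9) -> pd.DataFrame:
    """Emulate independent double coding of a random subset of videos.

    Returns a long table (trial_id, coder_id, duration_s) of total
    looking durations per trial: coder C1 reports the generated
    durations, coder C2 the same durations plus coder noise of SD
    ``config.sd_coder`` seconds.
    """
    config = dataset.config
    rng = _rng(config, 31)
    totals = []
    for df in (dataset.trials_exp1, dataset.trials_exp2):
        if len(df):
            t = df[df["includable"]]
            totals.append(pd.DataFrame({
                "trial_id": t["trial_id"],
                "duration_s": t["look_expression_s"] + t["look_neutral_s"],
            }))
    if len(dataset.trials_exp3):
        t = dataset.trials_exp3[dataset.trials_exp3["includable"]]
        look_cols = [f"look{i}_s" for i in range(1, 7)]
        totals.append(pd.DataFrame({
            "trial_id": t["trial_id"],
            "duration_s": t[look_cols].sum(axis=1, skipna=True),
        }))
    pool = pd.concat(totals, ignore_index=True)
    take = pool.iloc[rng.choice(len(pool), size=min(n_videos, len(pool)),
                                replace=False)]
    c1 = take.assign(coder_id="C1")
    noise = rng.normal(0.0, config.sd_coder, len(take))
    c2 = take.assign(coder_id="C2",
                     duration_s=np.maximum(take["duration_s"] + noise, 0.0))
    out = pd.concat([c1, c2], ignore_index=True)
    return out[["trial_id", "coder_id", "duration_s"]]


# ---------------------------------------------------------------------------
# file output: trial tables plus coded-event files in the coding_io dialect
# ---------------------------------------------------------------------------

def _events_and_manifest(dataset: SyntheticDataset):
    events = []
    manifest = []
    (w1s, w1d), (w2s, w2d) = EXP12_WINDOWS

    for experiment, df in (("exp1", dataset.trials_exp1), ("exp2", dataset.trials_exp2)):
        for _, t in df.iterrows():
            s1 = t["expr_side_win1"]
            s2 = "right" if s1 == "left" else "left"
            half_e = t["look_expression_s"] / 2.0
            half_n = t["look_neutral_s"] / 2.0
            for (ws, _wd), expr_side in (((w1s, w1d), s1), ((w2s, w2d), s2)):
                neut_side = "right" if expr_side == "left" else "left"
                cursor = ws
                if half_e > 0:
                    events.append((t["trial_id"], "C1", expr_side, cursor,
                                   cursor + half_e))
                    cursor += half_e
                if half_n > 0:
                    events.append((t["trial_id"], "C1", neut_side, cursor,
                                   cursor + half_n))
            manifest.append({
                "trial_id": t["trial_id"], "subject_id": t["subject_id"],
                "group_id": t["group_id"], "experiment": experiment,
                "expression": t["expression"],
                "intensity": t.get("intensity", ""),
                "sequence_expression": "", "violating_expression": "",
                "win1_start": w1s, "win1_dur": w1d,
                "win2_start": w2s, "win2_dur": w2d,
                "expr_side_win1": s1, "image_onsets": "", "image_dur": "",
            })

    onsets = [i * (EXP3_IMAGE_DUR + EXP3_GAP) for i in range(6)]
    onsets_str = ";".join(f"{o:g}" for o in onsets)
    for _, t in dataset.trials_exp3.iterrows():
        for i in range(6):
            look = t[f"look{i + 1}_s"]
            if pd.notna(look) and look > 0:
                events.append((t["trial_id"], "C1", "screen", onsets[i],
                               onsets[i] + look))
        manifest.append({
            "trial_id": t["trial_id"], "subject_id": t["subject_id"],
            "group_id": t["group_id"], "experiment": "exp3",
            "expression": "", "intensity": "",
            "sequence_expression": t["sequence_expression"],
            "violating_expression": t["violating_expression"],
            "win1_start": "", "win1_dur": "", "win2_start": "", "win2_dur": "",
            "expr_side_win1": "", "image_onsets": onsets_str,
            "image_dur": EXP3_IMAGE_DUR,
        })

    events_df = pd.DataFrame(events, columns=["trial_id", "coder_id", "target",
                                              "start_s", "stop_s"])
    manifest_df = pd.DataFrame(manifest)
    return events_df, manifest_df


def write_synthetic_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Write the dataset as CSV files round-trippable by the readers.

    Emits subjects.csv, maternal.csv, skills.csv (ground truth),
    trials_exp{1,2,3}.csv, and events.csv + manifest.csv in the coded
    looking-event dialect. Returns the mapping of logical name to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events, manifest = _events_and_manifest(dataset)
    tables = {
        "subjects": dataset.subjects,
        "maternal": dataset.maternal,
        "skills": dataset.skills,
        "trials_exp1": dataset.trials_exp1,
        "trials_exp2": dataset.trials_exp2,
        "trials_exp3": dataset.trials_exp3,
        "events": events,
        "manifest": manifest,
    }
    paths = {}
    for name, df in tables.items():
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    dataset.config.to_file(directory / "config.yaml")
    paths["config"] = directory / "config.yaml"
    return paths


def read_synthetic_dataset(directory) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_synthetic_dataset`."""
    directory = Path(directory)
    config = SimulationConfig.from_file(directory / "config.yaml")

    def rd(name, **kw):
        return pd.read_csv(directory / f"{name}.csv", **kw)

    subjects = rd("subjects", keep_default_na=False,
                  dtype={"mother_id": str})
    subjects["age_years"] = subjects["age_years"].astype(float)
    return SyntheticDataset(
        config=config,
        subjects=subjects,
        maternal=rd("maternal"),
        skills=rd("skills"),
        trials_exp1=rd("trials_exp1"),
        trials_exp2=rd("trials_exp2"),
        trials_exp3=rd("trials_exp3"),
    )
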