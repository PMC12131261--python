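"""Simulation configuration for synthetic study datasets.

The configuration encodes the study conditions the generator emulates:
a cohort of rhesus macaques (default 83 subjects in 15 social groups,
ages 1-16 years, majority female) tested in three looking-time
experiments, with maternal-care observation records (nine 10-minute
focals, scan samples every 30 s) available for roughly half of the
cohort. Effect-size fields are the ground truth that the downstream
pipeline is expected to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError

__all__ = ["AgeCurve", "SimulationConfig"]


@dataclass(frozen=True)
class AgeCurve:
    """Age trajectory of latent skill: linear rise up to ``knot_age``
    (default 5 years, the juvenile/adult boundary), flat thereafter.

    ``juvenile_slope`` is in skill units per year.
    """

    juvenile_slope: float = 0.17
    knot_age: float = 5.0

    def value(self, age_years):
        return self.juvenile_slope * np.minimum(np.asarray(age_years, float), self.knot_age)

    def mean_uniform(self, lo: float, hi: float) -> float:
        """Expected curve value when age ~ Uniform(lo, hi) (used to center skill)."""
        k = self.knot_age
        if hi <= k:
            return self.juvenile_slope * 0.5 * (lo + hi)
        if lo >= k:
            return self.juvenile_slope * k
        below = 0.5 * (lo + k) * (k - lo)
        above = k * (hi - k)
        return self.juvenile_slope * (below + above) / (hi - lo)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Attention-bias effects are signed deviations of the expected
    looking proportion from 0.5 (indifference); the intensity slope is
    the change in that proportion per unit of threat intensity on the
    0.25-1.0 scale; the violation excess is seconds added to the
    sixth-image looking time. Maternal-care coefficients act on latent
    skill with grooming/cradling expressed as percent of scan samples
    and approach/restrain as events per focal.
    """

    seed: int = 0

    # cohort
    n_subjects: int = 83
    n_groups: int = 15
    age_range: tuple[float, float] = (1.0, 16.0)
    prob_female: float = 56 / 83
    prob_maternal_data: float = 40 / 83

    # trials attempted per subject (with the default dropout these give
    # included-trial counts close to the emulated study's)
    trials_exp1: int = 2
    trials_exp2: int = 5
    trials_exp3: int = 1

    # attention-bias / violation effects (ground truth)
    effect_scream_bias: float = -0.07
    effect_bt_bias: float = 0.05
    effect_threat_bias: float = 0.01
    effect_intensity_slope: float = 0.12
    intensity_center: float = 0.625
    # skill-linked threat vigilance: more skilled subjects look toward the
    # threat avatar across all intensities (added per unit of skill factor
    # above the cohort mean; leaves the cohort-mean bias and the intensity
    # slope unchanged)
    effect_vigilance: float = 0.12
    effect_violation_excess: float = 0.27

    # maternal-care effects on latent skill
    beta_groom: float = 0.044      # per percent of scans groomed
    beta_cradle: float = 0.012     # per percent of scans cradled
    beta_approach: float = 1.426   # per approach per focal
    beta_restrain: float = -0.640  # per restraint per focal

    age_curve: AgeCurve = field(default_factory=AgeCurve)

    # random-effect and residual standard deviations of latent skill
    sd_group: float = 0.15
    sd_mother: float = 0.15
    sd_resid: float = 0.20

    # skill -> trial behavior link (multiplicative, exp scale)
    skill_link_scale: float = 0.9

    # trial-level noise
    sd_bias_trial: float = 0.12      # within-subject SD of the per-trial looking proportion
    # subjects also carry idiosyncratic stable biases (toward or away from a
    # stimulus class) whose magnitude scales with skill: strong
    # discriminators react strongly in a subject-specific direction, which
    # is what the absolute-bias composite score is designed to capture
    sd_bias_subject: float = 0.12
    total_look_mean: float = 6.0     # total looking seconds per paired trial
    total_look_sd: float = 1.5
    exp3_base_mean: float = 2.2      # first-image looking seconds
    exp3_base_sd: float = 0.35
    exp3_trend_mean: float = -0.15   # habituation decline, seconds per image
    exp3_trend_sd: float = 0.05
    sd_look_exp3: float = 0.30       # per-image looking noise, seconds
    missing_image_rate: float = 0.10  # exactly one of images 1-5 missed, still includable
    dropout_rate: float = 0.30       # trial fails the inclusion criteria

    # maternal observation protocol: nine 10-min focals, scans every 30 s
    n_focals: int = 9
    scans_per_focal: int = 20
    groom_beta_params: tuple[float, float] = (1.2, 10.8)
    cradle_beta_params: tuple[float, float] = (2.0, 3.7)
    approach_rate_mean: float = 0.5   # approaches per focal
    restrain_rate_mean: float = 0.15  # restraints per focal

    # double-coding emulation (inter-coder reliability)
    sd_coder: float = 1.2  # seconds of coder disagreement on a total duration

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        def fail(name: str, why: str):
            raise ConfigurationError(f"invalid configuration field {name!r}: {why}")

        if not (0 <= int(self.seed) < 2**31):
            fail("seed", "must be an integer in [0, 2**31)")
        for name in ("n_subjects", "n_groups", "trials_exp1", "trials_exp2",
                     "trials_exp3", "n_focals", "scans_per_focal"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                fail(name, "must be a non-negative integer")
        if self.n_subjects < 1:
            fail("n_subjects", "must be >= 1")
        if self.n_groups < 1 or self.n_groups > self.n_subjects:
            fail("n_groups", "must satisfy 1 <= n_groups <= n_subjects")
        lo, hi = self.age_range
        if not (lo >= 1.0 and hi > lo):
            fail("age_range", "requires 1 <= min < max (subjects are at least 1 year old)")
        for name in ("prob_female", "prob_maternal_data", "dropout_rate",
                     "missing_image_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                fail(name, "must be a probability in [0, 1]")
        for name in ("sd_group", "sd_mother", "sd_resid", "sd_bias_trial",
                     "sd_bias_subject",
                     "total_look_sd", "exp3_base_sd", "exp3_trend_sd",
                     "sd_look_exp3", "sd_coder"):
            if getattr(self, name) < 0:
                fail(name, "must be >= 0")
        if self.total_look_mean <= 0:
            fail("total_look_mean", "must be > 0")
        for name in ("groom_beta_params", "cradle_beta_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                fail(name, "beta shape parameters must be > 0")
        if self.approach_rate_mean < 0 or self.restrain_rate_mean < 0:
            fail("approach_rate_mean", "rates must be >= 0")

    # -- (de)serialization ------------------------------------------------
    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["groom_beta_params"] = list(self.groom_beta_params)
        d["cradle_beta_params"] = list(self.cradle_beta_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_curve" in d and isinstance(d["age_curve"], dict):
            d["age_curve"] = AgeCurve(**d["age_curve"])
        for key in ("age_range", "groom_beta_params", "cradle_beta_params"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a configuration from YAML or JSON."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
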