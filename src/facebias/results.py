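"""Lightweight result containers shared across analysis modules."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class TTestResult:
    """A one-sample or paired t-test result.

    ``sample_mean`` is the mean of the tested quantity (the mean bias
    proportion, or the mean observed-minus-predicted excess for the
    paired test); ``null_value`` is the value it is tested against.
    """

    statistic: float
    df: int
    p_value: float
    sample_mean: float
    null_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation between coders.

    ``form`` names the variant (default ICC2k: two-way random effects,
    absolute agreement, average of k raters' measurements).
    """

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    form: str
    n_units: int
    n_raters: int

    def to_dict(self) -> dict:
        return asdict(self)
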