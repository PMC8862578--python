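"""T' bone-density scoring and the comparative study arithmetic.

The T' score standardizes a vertebra's mean CT value against a reference
population of untreated vertebrae, exploiting the linear CT-BMD relationship
as a surrogate for a DXA T-score:

    T' = (measured CT value - reference mean CT value) / reference CT SD

A vertebra is classified osteoporotic when T' <= -2.5 (inclusive threshold).
Group-level scores follow by linearity: the T' mean shifts and scales the
group mean, the T' SD is the group SD divided by the reference SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

OSTEOPOROSIS_THRESHOLD = -2.5


@dataclass(frozen=True)
class TPrimeResult:
    ct_value: float
    ref_mean: float
    ref_sd: float
    t_prime: float = field(init=False)
    osteoporotic: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.ref_sd <= 0:
            raise ValueError("reference SD must be positive")
        tp = (self.ct_value - self.ref_mean) / self.ref_sd
        object.__setattr__(self, "t_prime", tp)
        object.__setattr__(self, "osteoporotic", tp <= OSTEOPOROSIS_THRESHOLD)


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- sample SD (n-1 denominator) of one study group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "GroupSummary":
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two values for a sample SD")
        return cls(n=int(arr.size), mean=float(arr.mean()),
                   sd=float(arr.std(ddof=1)))


def t_prime(ct_value: float, ref_mean: float, ref_sd: float) -> TPrimeResult:
    """Score one vertebral mean CT value against the reference population."""
    return TPrimeResult(ct_value=float(ct_value), ref_mean=float(ref_mean),
                        ref_sd=float(ref_sd))


def tprime_of_group(g: GroupSummary, ref_mean: float, ref_sd: float
                    ) -> tuple[float, float]:
    """(T' mean, T' SD) of a group, by linearity of the transform."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (g.mean - ref_mean) / ref_sd, g.sd / ref_sd


def reference_from_values(values: Iterable[float]) -> tuple[float, float]:
    """(mean, sample SD) of a set of untreated vertebral mean CT values."""
    g = GroupSummary.from_values(values)
    return g.mean, g.sd


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / b — how much a exceeds the baseline b, in percent."""
    if b == 0:
        raise ZeroDivisionError("baseline must be nonzero")
    return 100.0 * (a - b) / b


def percent_of(a: float, b: float) -> float:
    """100 * a / b — a as a percentage of the reference b."""
    if b == 0:
        raise ZeroDivisionError("reference must be nonzero")
    return 100.0 * a / b


_REQUIRED_GROUPS = ("decal_auto", "decal_manual", "control_manual", "reference")


def study_report(hu_groups: Mapping[str, GroupSummary],
                 force_groups: Mapping[str, GroupSummary] | None = None,
                 pre_decal: GroupSummary | None = None) -> dict:
    """Derived comparative table for the planning study.

    ``hu_groups`` maps group names to trajectory-HU summaries and must
    contain 'decal_auto' (automatic planning, decalcified), 'decal_manual',
    'control_manual' and 'reference' (whole-vertebra reference population;
    its mean/SD standardize the T' column). ``force_groups`` optionally
    carries pull-out forces for the same three planning groups, and
    ``pre_decal``/'decal_post' whole-vertebra HU summaries feed the T' rows.

    Percentages are reported to one decimal, T' values to two.
    """
    missing = [g for g in _REQUIRED_GROUPS if g not in hu_groups]
    if missing:
        raise KeyError(f"missing required group(s): {missing}")
    ref = hu_groups["reference"]
    auto = hu_groups["decal_auto"]
    man = hu_groups["decal_manual"]
    ctrl = hu_groups["control_manual"]

    report: dict = {
        "reference": {"n": ref.n, "mean_hu": ref.mean, "sd_hu": ref.sd},
        "trajectory_hu": {
            "auto_vs_manual_pct": round(percent_difference(auto.mean, man.mean), 1),
            "auto_vs_control_pct": round(percent_difference(auto.mean, ctrl.mean), 1),
        },
    }
    if pre_decal is not None:
        tp_mean, tp_sd = tprime_of_group(pre_decal, ref.mean, ref.sd)
        report["t_prime_pre_decalcification"] = {
            "mean": round(tp_mean, 2), "sd": round(tp_sd, 2)}
    if "decal_post" in hu_groups:
        post = hu_groups["decal_post"]
        tp_mean, tp_sd = tprime_of_group(post, ref.mean, ref.sd)
        report["t_prime_post_decalcification"] = {
            "mean": round(tp_mean, 2), "sd": round(tp_sd, 2),
            "osteoporotic": tp_mean <= OSTEOPOROSIS_THRESHOLD}
    if force_groups is not None:
        fa, fm, fc = (force_groups[k] for k in
                      ("decal_auto", "decal_manual", "control_manual"))
        report["pull_out_force"] = {
            # control exceeds the decalcified-manual baseline by this percent
            # (i.e. the decalcified-manual force deficit, relative to itself)
            "control_vs_decal_manual_pct_of_manual":
                round(percent_difference(fc.mean, fm.mean), 1),
            "auto_vs_manual_pct": round(percent_difference(fa.mean, fm.mean), 1),
            "auto_as_pct_of_control": round(percent_of(fa.mean, fc.mean), 1),
        }
    return report
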