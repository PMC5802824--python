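"""Complication index: severity scoring of a healing time course.

The index is the arithmetic mean of three day-49 symptom components:
a hamartoma score (fibrous-tissue fraction), a fibroblast-presence
score (saturating normalized fibroblast density) and a binary
non-union indicator (thresholded bone fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

from cpttrial.model import HealingTimeCourse, T_END, tissue_fractions

__all__ = [
    "CIComponents",
    "gamma_hamartoma",
    "gamma_fibroblasts",
    "gamma_nonunion",
    "complication_index",
    "score_time_course",
]

DEFAULT_UNION_THRESHOLD = 0.5
DEFAULT_FIBROBLAST_REF = 0.5


@dataclass(frozen=True)
class CIComponents:
    """The three symptom components and their mean (the complication index)."""

    gamma4: float  # hamartoma score in [0, 1]
    gamma5: float  # fibroblast-presence score in [0, 1]
    gamma6: int    # non-union indicator, 0 or 1
    gamma7: float  # complication index = mean of the three

    def __post_init__(self) -> None:
        for name in ("gamma4", "gamma5", "gamma7"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.gamma6 not in (0, 1):
            raise ValueError(f"gamma6 must be 0 or 1, got {self.gamma6}")
        expected = (self.gamma4 + self.gamma5 + self.gamma6) / 3.0
        if self.gamma7 != expected:
            raise ValueError("gamma7 is not the mean of the three components")


def gamma_nonunion(
    tc: HealingTimeCourse, union_threshold: float = DEFAULT_UNION_THRESHOLD
) -> int:
    """1 if the day-49 bone fraction is below the union threshold, else 0.

    A bone fraction exactly at the threshold counts as union.
    """
    if not 0.0 < union_threshold < 1.0:
        raise ValueError(f"union threshold {union_threshold} outside (0, 1)")
    _, _, bone = tissue_fractions(tc, T_END)
    return 0 if bone >= union_threshold else 1


def gamma_hamartoma(tc: HealingTimeCourse) -> float:
    """Day-49 fibrous-tissue fraction, clipped to [0, 1]."""
    fibrous, _, _ = tissue_fractions(tc, T_END)
    return min(1.0, max(0.0, fibrous))


def gamma_fibroblasts(
    tc: HealingTimeCourse, c_ref: float = DEFAULT_FIBROBLAST_REF
) -> float:
    """Day-49 fibroblast density normalized by ``c_ref``, saturating at 1."""
    if c_ref <= 0:
        raise ValueError(f"c_ref must be positive, got {c_ref}")
    return min(1.0, float(tc.c_f[tc._day_index(T_END)]) / c_ref)


def complication_index(g4: float, g5: float, g6: float) -> float:
    """Arithmetic mean of the three symptom components."""
    for name, val in (("gamma4", g4), ("gamma5", g5), ("gamma6", g6)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [0, 1]")
    return (g4 + g5 + g6) / 3.0


def score_time_course(
    tc: HealingTimeCourse,
    union_threshold: float = DEFAULT_UNION_THRESHOLD,
    c_ref: float = DEFAULT_FIBROBLAST_REF,
) -> CIComponents:
    """Compute all severity components for one subject-arm trajectory."""
    g4 = gamma_hamartoma(tc)
    g5 = gamma_fibroblasts(tc, c_ref)
    g6 = gamma_nonunion(tc, union_threshold)
    return CIComponents(
        gamma4=g4, gamma5=g5, gamma6=g6, gamma7=complication_index(g4, g5, g6)
    )
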