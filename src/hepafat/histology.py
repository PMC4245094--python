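"""Histologic reference standard: steatosis grading, steatohepatitis, fibrosis.

Steatosis is scored as the percentage of steatotic hepatocytes, in 5%
increments, and banded per the NASH-CRN scheme: none (<5%), mild (5-33%),
moderate (33-66%), severe (>66%). The printed bands share their endpoints, so
a boundary convention is required: 5 -> mild, 33 -> moderate, 66 -> moderate,
>66 -> severe (half-open, exhaustive). Steatohepatitis and fibrosis stage
(F0-F4) are supplied flags, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GRADES",
    "FIBROSIS_STAGES",
    "CUTPOINTS",
    "BiopsyResult",
    "grade_steatosis",
    "grade_rank",
    "binary_labels",
]

GRADES = ("none", "mild", "moderate", "severe")
FIBROSIS_STAGES = ("F0", "F1", "F2", "F3", "F4")
#: Ordinal dichotomization cutpoints: label -> minimal grade rank counted positive.
CUTPOINTS = {"mild": 1, "moderate": 2, "severe": 3}


def grade_steatosis(percent: float) -> str:
    """Band a steatotic-hepatocyte percentage into a NASH-CRN grade."""
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"steatosis percent {percent} outside [0, 100]")
    if percent < 5.0:
        return "none"
    if percent < 33.0:
        return "mild"
    if percent <= 66.0:
        return "moderate"
    return "severe"


def grade_rank(grade: str) -> int:
    """Ordinal rank of a grade: none=0 ... severe=3."""
    try:
        return GRADES.index(grade)
    except ValueError:
        raise ValueError(f"unknown steatosis grade {grade!r}") from None


def binary_labels(grades: Iterable[str], cutpoint: str) -> np.ndarray:
    """One-vs-rest dichotomization at a named cutpoint (>= that grade).

    ``cutpoint="mild"`` labels any steatosis positive; ``"severe"`` only
    severe steatosis.
    """
    if cutpoint not in CUTPOINTS:
        raise ValueError(f"cutpoint must be one of {sorted(CUTPOINTS)}, got {cutpoint!r}")
    threshold = CUTPOINTS[cutpoint]
    return np.array([int(grade_rank(g) >= threshold) for g in grades])


@dataclass
class BiopsyResult:
    """One subject's histology: steatosis %, grade, NASH flag, fibrosis stage."""

    steatosis_percent: float
    grade: str
    steatohepatitis: bool
    fibrosis_stage: str
    siderosis: bool = False

    def __post_init__(self) -> None:
        if self.steatosis_percent % 5 != 0:
            raise ValueError("steatosis percent must be a multiple of 5")
        expected = grade_steatosis(self.steatosis_percent)
        if self.grade != expected:
            raise ValueError(
                f"grade {self.grade!r} inconsistent with "
                f"{self.steatosis_percent}% (expected {expected!r})"
            )
        if self.fibrosis_stage not in FIBROSIS_STAGES:
            raise ValueError(f"unknown fibrosis stage {self.fibrosis_stage!r}")
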