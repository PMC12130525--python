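"""Age-conditional empirical telomere-length percentiles.

Builds a nonparametric reference from control telomere measurements
(excluding rare-variant carriers, who would drag the reference down) and
scores cases by their mid-rank percentile among controls within an age
window (default +/- 5 years, at least 20 controls).  Percentiles are
clipped to [100/(m+1), 100*m/(m+1)] so that a case outside the control
range is reported at the resolution the window supports rather than at
0 or 100.  Scoring controls against their own reference yields
approximately uniform percentiles, which is the calibration property the
tests check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TLRecord:
    """One telomere-length measurement on any consistent scale."""

    sample: str
    age: float  # years
    measure: float
    rare_variant_carrier: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not math.isfinite(self.measure):
            raise ValueError("measure must be finite")


@dataclass
class TLReference:
    """Control records post-exclusion, with the windowing parameters."""

    records: list[TLRecord]
    age_half_width: float = 5.0
    min_window_count: int = 20
    _ages: np.ndarray = field(init=False, repr=False)
    _measures: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._ages = np.array([r.age for r in self.records], dtype=float)
        self._measures = np.array([r.measure for r in self.records], dtype=float)

    @property
    def n_controls(self) -> int:
        return len(self.records)


def build_reference(
    controls: list[TLRecord],
    exclude_carriers: bool = True,
    age_half_width: float = 5.0,
    min_window_count: int = 20,
) -> TLReference:
    """Retain non-carrier controls and store windowing parameters.

    Exclusion only removes records; retained measures are untouched.
    """
    kept = [r for r in controls if not (exclude_carriers and r.rare_variant_carrier)]
    if not kept:
        raise ValueError("no controls remain after rare-variant-carrier exclusion")
    return TLReference(
        records=kept, age_half_width=age_half_width, min_window_count=min_window_count
    )


def percentile_of(ref: TLReference, age: float, measure: float) -> float:
    """Empirical mid-rank percentile of ``measure`` at ``age``.

    Controls within ``|control age - age| <= half-width`` form the
    comparison set of size m (an error names the age if m is below the
    minimum); the percentile is 100*(below + 0.5*ties)/m clipped to
    [100/(m+1), 100*m/(m+1)].
    """
    in_window = np.abs(ref._ages - age) <= ref.age_half_width
    m = int(in_window.sum())
    if m < ref.min_window_count:
        raise ValueError(
            f"only {m} controls within +/-{ref.age_half_width} years of age {age}"
            f" (minimum {ref.min_window_count})"
        )
    vals = ref._measures[in_window]
    below = int((vals < measure).sum())
    ties = int((vals == measure).sum())
    p = 100.0 * (below + 0.5 * ties) / m
    return float(np.clip(p, 100.0 / (m + 1), 100.0 * m / (m + 1)))


def flag_below(
    ref: TLReference, cases: list[TLRecord], threshold: float = 10.0
) -> dict[str, tuple[float, bool]]:
    """Percentile and below-threshold flag per case, keyed by sample id."""
    out: dict[str, tuple[float, bool]] = {}
    for case in cases:
        p = percentile_of(ref, case.age, case.measure)
        out[case.sample] = (p, p < threshold)
    return out
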