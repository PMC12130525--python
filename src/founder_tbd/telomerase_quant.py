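"""Quantification of telomerase direct-assay gels.

A direct assay resolves the products of telomerase-mediated primer
extension on a high-resolution gel; each prominent band is the addition
of one TTAGGG repeat.  Under a constant per-repeat dissociation
probability ``d`` the band intensities follow a geometric decay,

    I(n) = A * c(n) * d * (1 - d)**(n - 1),

where ``c(n)`` corrects for label incorporation (by default proportional
to product length, ``c(n) = n``).  Fitting ``ln(I(n)/c(n))`` against
``n`` gives slope ``ln(1 - d)``; repeat-addition processivity is
reported as the mean of the geometric law, ``1/d`` — the average number
of repeats synthesized before the enzyme dissociates.  The fit also
exposes the decay constant and the median product length, the other two
conventions in use for this quantity.

Activity is total lane signal over the loading control, normalized to
the amount of telomerase RNA (hTR) recovered in the immunoprecipitate,
expressed as percent of the wild-type lane.  Assembly (hTR bound per
hTERT) follows the chain
``((ip_htr/wt)/(ip_htert/wt)) / (lysate_htr/wt)`` so that expression
differences in the lysate cancel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats


@dataclass
class GelLane:
    """Per-repeat band intensities with loading-control and recovery metadata.

    ``intensities[k]`` is the band for repeat number ``n = k + 1``.
    """

    intensities: np.ndarray
    lc: float  # loading-control band
    ip_htr: float  # hTR recovered in the IP eluate
    ip_htert: float  # hTERT recovered in the IP eluate
    lysate_htr: float  # hTR in the input lysate
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("band intensities must be non-negative")
        if self.lc <= 0:
            raise ValueError("loading control must be positive")

    @property
    def n_max(self) -> int:
        return len(self.intensities)


@dataclass
class ProcessivityEstimate:
    """Result of the log-linear decay fit on one lane."""

    dissociation_prob: float  # d-hat in (0, 1)
    processivity: float  # 1 / d-hat, mean repeats before dissociation
    slope: float
    intercept: float
    r_squared: float
    fit_window: tuple[int, int]
    decay_constant: float  # -slope, per repeat
    median_repeats: float  # median of the geometric law

    def __post_init__(self) -> None:
        if not 0.0 < self.dissociation_prob < 1.0:
            raise ValueError("dissociation probability must lie in (0, 1)")
        if self.processivity < 1.0:
            raise ValueError("processivity below one repeat")


@dataclass
class ComparisonReport:
    """Replicate comparison of a variant against wild type."""

    variant_label: str
    mean_percent_of_wt: float
    sem_percent_of_wt: float
    reduction_percent: float
    p_value: float
    n_replicates: int
    n_wt_replicates: int
    sem_defined: bool


def normalize_assembly(
    ip_htr: float,
    ip_htert: float,
    lysate_htr: float,
    wt_refs: tuple[float, float, float],
) -> float:
    """Telomerase assembly ratio relative to wild type.

    ``wt_refs`` is ``(wt_ip_htr, wt_ip_htert, wt_lysate_htr)``.  The
    ratio is hTR-per-hTERT in the eluate, each as a fraction of WT, then
    normalized to lysate hTR so plasmid expression differences cancel.
    """
    wt_ip_htr, wt_ip_htert, wt_lysate_htr = wt_refs
    if min(wt_ip_htr, wt_ip_htert, wt_lysate_htr) <= 0:
        raise ValueError("wild-type reference values must be positive")
    rel_htr = ip_htr / wt_ip_htr
    rel_htert = ip_htert / wt_ip_htert
    rel_lysate = lysate_htr / wt_lysate_htr
    return (rel_htr / rel_htert) / rel_lysate


def quantify_activity(lane: GelLane, wt_lane: GelLane) -> float:
    """Lane activity as percent of the wild-type lane.

    Total band signal over the loading control, normalized to recovered
    hTR, expressed relative to the same quantity for WT.
    """
    def specific(l: GelLane) -> float:
        if l.ip_htr <= 0:
            raise ValueError("recovered hTR must be positive")
        return (float(l.intensities.sum()) / l.lc) / l.ip_htr

    wt = specific(wt_lane)
    if wt == 0:
        raise ValueError("wild-type lane has zero total signal")
    return 100.0 * specific(lane) / wt


def estimate_processivity(
    lane: GelLane,
    fit_window: tuple[int, int] | None = None,
    label_correction: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ProcessivityEstimate:
    """Fit the geometric decay of band intensities and report 1/d.

    ``fit_window`` is an inclusive repeat-number range; the default
    excludes ``n = 1`` (initiation artifacts) and runs to the last band.
    Requires at least 5 positive bands inside the window; a non-negative
    slope (no decay) is rejected.
    """
    n = np.arange(1, lane.n_max + 1)
    c = label_correction(n.astype(float)) if label_correction else n.astype(float)
    lo, hi = fit_window if fit_window is not None else (2, lane.n_max)
    use = (n >= lo) & (n <= hi) & (lane.intensities > 0) & (c > 0)
    if use.sum() < 5:
        raise ValueError(f"fewer than 5 usable bands in fit window [{lo}, {hi}]")
    y = np.log(lane.intensities[use] / c[use])
    fit = stats.linregress(n[use], y)
    if fit.slope >= 0:
        raise ValueError(f"non-negative decay slope ({fit.slope:.4g}): not a dissociation signal")
    d = 1.0 - math.exp(fit.slope)
    return ProcessivityEstimate(
        dissociation_prob=d,
        processivity=1.0 / d,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        fit_window=(lo, hi),
        decay_constant=-float(fit.slope),
        median_repeats=math.log(0.5) / math.log1p(-d),
    )


def compare_variants(
    variant_values: Sequence[float],
    wt_values: Sequence[float],
    label: str = "variant",
) -> ComparisonReport:
    """Compare replicate measurements of a variant against wild type.

    Each replicate is expressed as percent of the WT replicate mean;
    significance is a two-sided Welch t-test on the raw values.  With a
    single variant replicate the SEM is undefined and flagged.
    """
    v = np.asarray(variant_values, dtype=float)
    w = np.asarray(wt_values, dtype=float)
    if len(w) < 1 or len(v) < 1:
        raise ValueError("both groups need at least one replicate")
    wt_mean = w.mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean is zero")
    pct = 100.0 * v / wt_mean
    sem_defined = len(v) >= 2
    sem = float(stats.sem(pct)) if sem_defined else math.nan

    if v.std() == 0 and w.std() == 0:
        # Welch is indeterminate on two constant groups.
        p = 1.0 if v.mean() == w.mean() else 0.0
    else:
        with warnings.catch_warnings():
            # one constant group triggers scipy's precision-loss warning
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(v, w, equal_var=False).pvalue)
    mean_pct = float(pct.mean())
    return ComparisonReport(
        variant_label=label,
        mean_percent_of_wt=mean_pct,
        sem_percent_of_wt=sem,
        reduction_percent=100.0 - mean_pct,
        p_value=p,
        n_replicates=len(v),
        n_wt_replicates=len(w),
        sem_defined=sem_defined,
    )


def plot_decay_fit(lane: GelLane, estimate: ProcessivityEstimate, path: str) -> None:
    """Save a diagnostic plot of the log-linear decay fit (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = np.arange(1, lane.n_max + 1)
    c = n.astype(float)
    pos = lane.intensities > 0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(n[pos], np.log(lane.intensities[pos] / c[pos]), "o", label="bands")
    lo, hi = estimate.fit_window
    xs = np.array([lo, hi], dtype=float)
    ax.plot(xs, estimate.intercept + estimate.slope * xs, "-",
            label=f"fit: 1/d = {estimate.processivity:.2f}")
    ax.set_xlabel("repeat number n")
    ax.set_ylabel("ln(I(n) / n)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
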