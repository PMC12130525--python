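"""Screening panels for the founder haplotype and fold-enrichment arithmetic.

Two screens mirror the two control analyses a founder-variant study runs:

* **Phased screen** — counts individual haplotypes (not individuals) that
  carry the alternate allele at every marker SNV *and* the reference
  allele at the target: the founder marker string riding on a wild-type
  chromosome.  Finding zero such haplotypes among controls shows the
  markers exist nowhere except on the founder chromosome.
* **Unphased screen** — classifies every sample lacking the target alt
  allele by genotype-level marker presence (cis cannot be verified
  without phase): *full* when at least one alt allele is present at
  every marker site, *partial* when not full but both flanking markers
  carry an alt, *none* otherwise.  Missing genotypes count as
  alt-absent, which is conservative: missingness can only deflate
  founder-haplotype counts, never inflate them.

Carriers themselves are classified the same way (a carrier retaining
every marker shows full haplotype conservation; one retaining only the
flanks, partial).  Fold enrichment of a subpopulation allele frequency
over the global one rounds to significant figures for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .haplotype_core import MarkerSet
from .panel import MISSING, GenotypePanel, PhasedPanel


def localize_markers(
    markers: MarkerSet, panel: PhasedPanel | GenotypePanel
) -> MarkerSet:
    """Re-map marker and target site indices onto ``panel``'s site order.

    Sites are matched on (chrom, pos, ref, alt); any marker or target
    absent from the panel is an error listing the missing sites.
    """
    keys = {s.key(): i for i, s in enumerate(panel.sites)}
    missing = [
        f"{s.chrom}:{s.pos}:{s.ref}>{s.alt}"
        for s in [*markers.markers, markers.target]
        if s.key() not in keys
    ]
    if missing:
        raise ValueError(f"marker sites absent from panel: {', '.join(missing)}")
    return replace(
        markers,
        marker_indices=[keys[m.key()] for m in markers.markers],
        target_index=keys[markers.target.key()],
    )


@dataclass
class HaplotypeCall:
    """Marker-content classification of one sample (or haplotype)."""

    sample: str
    cls: str  # "full" | "partial" | "none"
    markers_present: list[int]  # panel site indices with >= 1 alt allele
    flanks_present: tuple[bool, bool]
    indeterminate: bool = False  # both flank genotypes missing

    def __post_init__(self) -> None:
        if self.cls not in ("full", "partial", "none"):
            raise ValueError(f"invalid class {self.cls!r}")
        if self.cls == "full" and not all(self.flanks_present):
            raise ValueError("full call without both flanks present")


@dataclass
class ScreenCounts:
    """Tallies of a screen; full + partial-only + none = screened."""

    n_screened: int
    n_full: int
    n_partial_only: int
    n_none: int
    phased_haplotype_hits: int | None = None
    calls: list[HaplotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_full + self.n_partial_only + self.n_none != self.n_screened:
            raise ValueError("screen counts do not partition the screened set")


def classify_carrier(
    genotypes: np.ndarray, markers: MarkerSet, sample: str = ""
) -> HaplotypeCall:
    """Classify one genotype vector by founder-marker presence.

    ``genotypes`` is the allele-count vector over panel sites (0/1/2,
    -1 missing); requires the flank pair to be defined.  Missing
    genotypes count as alt-absent.  Both flank genotypes missing makes
    the call indeterminate (flagged, classed "none").
    """
    g = np.asarray(genotypes)
    left_idx, right_idx = markers.flank_indices
    present = [j for j in markers.marker_indices if g[j] >= 1]
    flanks = (g[left_idx] >= 1, g[right_idx] >= 1)
    indeterminate = g[left_idx] == MISSING and g[right_idx] == MISSING
    if len(present) == len(markers.marker_indices) and len(present) > 0:
        cls = "full"
    elif flanks[0] and flanks[1]:
        cls = "partial"
    else:
        cls = "none"
    return HaplotypeCall(
        sample=sample,
        cls=cls,
        markers_present=present,
        flanks_present=(bool(flanks[0]), bool(flanks[1])),
        indeterminate=bool(indeterminate),
    )


def phased_haplotype_screen(panel: PhasedPanel, markers: MarkerSet) -> ScreenCounts:
    """Count haplotypes carrying the full marker string in cis with a WT target.

    A hit carries alt at every marker site and ref at the target.  All
    marker sites and the target must be present in the panel.
    """
    markers = localize_markers(markers, panel)
    idx = np.array(markers.marker_indices, dtype=int)
    H = panel.haplotypes
    ref_at_target = H[:, markers.target_index] == 0
    all_markers = (H[:, idx] == 1).all(axis=1) if len(idx) else np.zeros(len(H), bool)
    full = all_markers & ref_at_target
    left_idx, right_idx = markers.flank_indices
    flanks_only = (
        (H[:, left_idx] == 1) & (H[:, right_idx] == 1) & ref_at_target & ~full
    )
    n_full = int(full.sum())
    n_partial = int(flanks_only.sum())
    n = H.shape[0]
    return ScreenCounts(
        n_screened=n,
        n_full=n_full,
        n_partial_only=n_partial,
        n_none=n - n_full - n_partial,
        phased_haplotype_hits=n_full,
    )


def unphased_control_screen(
    genotypes: GenotypePanel, markers: MarkerSet, require_no_target_alt: bool = True
) -> ScreenCounts:
    """Classify samples by marker presence; by default only target-ref samples.

    With ``require_no_target_alt`` (the control screen) samples carrying
    the target alt are excluded; disabling it screens a carrier panel for
    haplotype conservation instead.
    """
    markers = localize_markers(markers, genotypes)
    calls: list[HaplotypeCall] = []
    t = markers.target_index
    for i, sample in enumerate(genotypes.samples):
        g = genotypes.genotypes[i]
        if require_no_target_alt and g[t] >= 1:
            continue
        calls.append(classify_carrier(g, markers, sample=sample))
    n_full = sum(c.cls == "full" for c in calls)
    n_partial = sum(c.cls == "partial" for c in calls)
    return ScreenCounts(
        n_screened=len(calls),
        n_full=n_full,
        n_partial_only=n_partial,
        n_none=len(calls) - n_full - n_partial,
        calls=calls,
    )


def maf_fold_enrichment(
    af_subpop: float, af_global: float, sig_figs: int | None = None
) -> float:
    """Fold enrichment of a subpopulation allele frequency over the global one.

    Optionally rounded to ``sig_figs`` significant figures (the form a
    study quotes, e.g. "~40-fold").
    """
    if af_global <= 0:
        raise ValueError("global allele frequency must be positive: enrichment undefined")
    fold = af_subpop / af_global
    if sig_figs is None or fold == 0:
        return fold
    exponent = math.floor(math.log10(abs(fold)))
    return round(fold, -exponent + sig_figs - 1)
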