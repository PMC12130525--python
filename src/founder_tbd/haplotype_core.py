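"""Shared-haplotype delimitation and rare in-cis marker distillation.

Given a phased panel and a target variant, this module extracts every
variant-bearing haplotype, walks outward from the target to delimit the
maximal contiguous block of sites on which all carrier haplotypes agree
(an identity-by-state block, which always contains the true
identity-by-descent segment), and filters the block down to the rare
(global MAF below a threshold) SNVs whose alternate allele rides on the
founder haplotype — the markers that define a founder haplotype, with the
pair flanking the target singled out.

Conventions: block boundaries are the positions of the outermost agreeing
sites (not midpoints to the first discrepancy); missing calls are
non-informative and never break agreement; homozygous carriers contribute
both haplotypes and both must agree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, PhasedPanel, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class CarrierHaplotype:
    """One variant-bearing haplotype of a carrier sample."""

    sample: str
    hap_index: int  # 0 or 1
    alleles: np.ndarray  # allele vector over panel sites
    target_index: int
    carries_target: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if not self.carries_target:
            raise ValueError(f"{self.sample} hap{self.hap_index} does not carry the target")


@dataclass
class SharedBlock:
    """Maximal interval around the target on which all carriers agree.

    ``start``/``end`` are 1-based inclusive positions of the outermost
    agreeing sites; ``member_indices`` the panel site indices inside the
    block; ``shared_alleles`` the agreed allele at each member site.
    """

    chrom: str
    start: int
    end: int
    member_indices: np.ndarray
    shared_alleles: np.ndarray
    target_index: int
    n_carriers: int

    @property
    def span(self) -> int:
        return interval_span(self.start, self.end)


@dataclass
class MarkerSet:
    """Rare in-cis SNVs defining the founder haplotype, plus flanks.

    Markers are the block SNVs whose founder-haplotype allele is the alt
    allele and whose global AF is below the threshold; the target variant
    itself is kept separate.  ``left_flank``/``right_flank`` are the
    markers nearest the target on each side (None when a side has no
    marker, in which case ``flanks_defined`` is False).
    """

    markers: list[VariantSite]
    marker_indices: list[int]  # panel site indices, sorted by position
    target: VariantSite
    target_index: int
    left_flank: VariantSite | None = None
    right_flank: VariantSite | None = None
    threshold: float = 0.01

    def __post_init__(self) -> None:
        pos = [m.pos for m in self.markers]
        if pos != sorted(pos):
            raise ValueError("markers must be sorted by position")

    @property
    def flanks_defined(self) -> bool:
        return self.left_flank is not None and self.right_flank is not None

    @property
    def flank_indices(self) -> tuple[int, int]:
        if not self.flanks_defined:
            raise ValueError("flanks undefined: missing a marker on one side of the target")
        left = self.marker_indices[self.markers.index(self.left_flank)]
        right = self.marker_indices[self.markers.index(self.right_flank)]
        return left, right


def carrier_haplotypes(panel: PhasedPanel, target: VariantSite) -> list[CarrierHaplotype]:
    """Extract one :class:`CarrierHaplotype` per alt-bearing haplotype.

    Homozygous carriers contribute both haplotypes.  Carriers whose target
    genotype is unphased are excluded with a logged warning; a target
    absent from the panel is an error.
    """
    t = panel.find_site(target)
    out: list[CarrierHaplotype] = []
    for i, sample in enumerate(panel.samples):
        haps = panel.sample_haplotypes(i)
        alt_haps = [k for k in range(2) if haps[k, t] == 1]
        if not alt_haps:
            continue
        if not panel.is_phased(i, t):
            logger.warning(
                "carrier %s excluded: target %s:%d unphased", sample, target.chrom, target.pos
            )
            continue
        for k in alt_haps:
            out.append(
                CarrierHaplotype(sample=sample, hap_index=k, alleles=haps[k], target_index=t)
            )
    return out


def shared_block(
    carriers: list[CarrierHaplotype], panel_sites: list[VariantSite]
) -> SharedBlock:
    """Delimit the maximal contiguous agreeing block around the target.

    A site "agrees" when every carrier haplotype with a non-missing call
    carries the same allele there (sites missing in all carriers also
    agree, vacuously).  The block runs from the outermost agreeing site
    before the first disagreement on the left of the target to its
    counterpart on the right.
    """
    if not carriers:
        raise ValueError("shared_block requires at least one carrier haplotype")
    t = carriers[0].target_index
    if any(c.target_index != t for c in carriers):
        raise ValueError("carriers disagree on the target site index")
    H = np.stack([c.alleles for c in carriers])  # (C, S)

    called = H != MISSING
    any_called = called.any(axis=0)
    # A site disagrees iff two non-missing calls differ.
    first = np.where(
        any_called, H[np.argmax(called, axis=0), np.arange(H.shape[1])], 0
    )
    mismatch = (called & (H != first[None, :])).any(axis=0)

    left = t
    while left > 0 and not mismatch[left - 1]:
        left -= 1
    right = t
    while right < H.shape[1] - 1 and not mismatch[right + 1]:
        right += 1

    member = np.arange(left, right + 1)
    shared = np.where(any_called[member], first[member], MISSING).astype(np.int8)
    return SharedBlock(
        chrom=panel_sites[t].chrom,
        start=panel_sites[left].pos,
        end=panel_sites[right].pos,
        member_indices=member,
        shared_alleles=shared,
        target_index=t,
        n_carriers=len(carriers),
    )


def filter_rare_snvs(
    block: SharedBlock,
    panel_sites: list[VariantSite],
    af_table: dict[tuple[str, int, str, str], float] | None = None,
    threshold: float = 0.01,
) -> MarkerSet:
    """Distill the block to rare in-cis marker SNVs.

    A block site is a marker when the founder-haplotype (shared) allele is
    the alt allele, the site is a SNV, and its global AF is below
    ``threshold``.  AF comes from ``af_table`` (keyed on chrom, pos, ref,
    alt) when given, else from the site's own annotation; a missing AF is
    treated as common (site excluded) with a warning.  Flanks are the
    markers nearest the target on each side; a side with no marker leaves
    the flank pair undefined (flagged via ``flanks_defined``).
    """
    target = panel_sites[block.target_index]
    markers: list[VariantSite] = []
    indices: list[int] = []
    for j, allele in zip(block.member_indices, block.shared_alleles):
        if j == block.target_index or allele != 1:
            continue
        site = panel_sites[j]
        if not site.is_snv:
            continue
        af = site.global_af
        if af_table is not None and site.key() in af_table:
            af = af_table[site.key()]
        if math.isnan(af):
            logger.warning(
                "site %s:%d has no AF annotation; treated as common", site.chrom, site.pos
            )
            continue
        if af < threshold:
            markers.append(site)
            indices.append(int(j))

    left = [m for m in markers if m.pos < target.pos]
    right = [m for m in markers if m.pos > target.pos]
    left_flank = left[-1] if left else None
    right_flank = right[0] if right else None
    if left_flank is None or right_flank is None:
        logger.warning(
            "flank pair undefined: %d markers left, %d right of target", len(left), len(right)
        )
    return MarkerSet(
        markers=markers,
        marker_indices=indices,
        target=target,
        target_index=block.target_index,
        left_flank=left_flank,
        right_flank=right_flank,
        threshold=threshold,
    )


def interval_span(start: int, end: int) -> int:
    """Width in bp of a 1-based inclusive interval: ``end - start + 1``."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1
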