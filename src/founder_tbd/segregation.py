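"""Pedigree-based phasing and co-segregation testing within families.

Families with several genotyped members let the variant-bearing parental
haplotype be determined without statistical phasing: Mendelian deduction
at the target, refined where needed by a linked polymorphic
microsatellite, assigns each carrier child's variant to its paternal or
maternal chromosome.  Co-segregation then asks, meiosis by meiosis,
whether the founder marker alleles (rare SNVs plus the linked
microsatellite) travelled with the variant: a single recombinant child
(markers without variant, or variant without markers) breaks
co-segregation.

Microsatellite alleles are matched by exact repeat count; a one-step
difference is reported as a possible stepwise mutation rather than a
co-segregation failure, since single-repeat slippage is the dominant STR
error mode.  Individuals with unknown carrier status are skipped, never
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .haplotype_core import MarkerSet
from .panel import MISSING, VariantSite

FOUNDER_PARENT = "0"  # PED convention for "no parent in pedigree"


class MendelianError(ValueError):
    """A child allele absent from both parents, naming individual and site."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str = FOUNDER_PARENT
    mother: str = FOUNDER_PARENT
    sex: int = 0  # 1 male, 2 female, 0 unknown
    carrier_status: int | None = None  # target-allele copies, None = unknown


@dataclass
class Pedigree:
    """One family: individuals with resolvable parent links and no cycles."""

    fid: str
    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent != FOUNDER_PARENT and parent not in self.individuals:
                    raise ValueError(f"{ind.iid}: parent {parent} not in pedigree {self.fid}")
        # cycle check by walking ancestors
        for iid in self.individuals:
            seen = set()
            stack = [iid]
            while stack:
                cur = stack.pop()
                ind = self.individuals[cur]
                for parent in (ind.father, ind.mother):
                    if parent == FOUNDER_PARENT:
                        continue
                    if parent == iid:
                        raise ValueError(f"{iid} is its own ancestor in {self.fid}")
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    def children_of(self, parent_iid: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals.values()
            if parent_iid in (ind.father, ind.mother)
        ]


@dataclass
class FamilyGenotypes:
    """Unphased genotypes at SNV sites plus microsatellite repeat counts.

    ``genotypes[iid]`` is an allele-count vector (0/1/2, -1 missing) over
    ``sites``; ``microsatellites[iid][locus]`` an unordered repeat-count
    pair.
    """

    sites: list[VariantSite]
    genotypes: dict[str, np.ndarray]
    microsatellites: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iid, g in self.genotypes.items():
            g = np.asarray(g, dtype=np.int8)
            if g.shape != (len(self.sites),):
                raise ValueError(f"{iid}: genotype vector length mismatch")
            if not np.all(np.isin(g, [-1, 0, 1, 2])):
                raise ValueError(f"{iid}: genotype values must be in {{0,1,2,missing}}")
            self.genotypes[iid] = g
        for iid, loci in self.microsatellites.items():
            for locus, (a, b) in loci.items():
                if a < 1 or b < 1:
                    raise ValueError(f"{iid} {locus}: repeat counts must be positive")

    def site_index(self, site: VariantSite) -> int:
        for i, s in enumerate(self.sites):
            if s.key() == site.key():
                return i
        raise KeyError(f"site {site.chrom}:{site.pos} not in family genotypes")


@dataclass
class SegregationReport:
    """Outcome of a within-family co-segregation test."""

    cosegregates: bool | None  # None when no informative meiosis (flagged)
    n_informative_meioses: int
    meioses: list[dict]
    mendelian_errors: list[str]
    notes: list[str] = field(default_factory=list)


def _transmittable(gt: int) -> set[int]:
    """Alleles a parent with unphased genotype gt can transmit."""
    return {0: {0}, 1: {0, 1}, 2: {1}}.get(gt, {0, 1})  # missing: either


def phase_target_by_pedigree(
    fam: FamilyGenotypes,
    ped: Pedigree,
    target: VariantSite,
    linked_str: str | None = None,
    founder_str_allele: int | None = None,
) -> dict[str, str]:
    """Parental origin of the variant for each carrier child.

    Returns ``{"paternal" | "maternal" | "both" | "ambiguous"}`` per
    carrier child with both parents in the pedigree, by Mendelian
    deduction at the target.  When both parents are heterozygous the
    linked microsatellite (``linked_str``) is brought in and all joint
    phase/transmission configurations are enumerated; the origin is
    reported only when every consistent configuration agrees.  Giving
    ``founder_str_allele`` (the repeat count riding on the candidate
    founder haplotype) constrains the enumeration further: a parent
    carrying both the variant and the founder repeat is assumed to carry
    them in cis.  A child allele absent from both parents raises
    :class:`MendelianError`.
    """
    t = fam.site_index(target)
    origins: dict[str, str] = {}
    for ind in ped.individuals.values():
        if ind.father == FOUNDER_PARENT or ind.mother == FOUNDER_PARENT:
            continue
        if ind.iid not in fam.genotypes:
            continue
        child_gt = int(fam.genotypes[ind.iid][t])
        if child_gt <= 0:  # non-carrier or missing
            continue
        f_gt = int(fam.genotypes[ind.father][t]) if ind.father in fam.genotypes else MISSING
        m_gt = int(fam.genotypes[ind.mother][t]) if ind.mother in fam.genotypes else MISSING

        consistent: set[str] = set()
        pairs = [(1, 1)] if child_gt == 2 else [(1, 0), (0, 1)]
        for pat_a, mat_a in pairs:
            if pat_a in _transmittable(f_gt) and mat_a in _transmittable(m_gt):
                consistent.add(
                    "both" if (pat_a, mat_a) == (1, 1) else ("paternal" if pat_a == 1 else "maternal")
                )
        if not consistent:
            raise MendelianError(
                f"{ind.iid}: allele at {target.chrom}:{target.pos} absent from both parents"
            )
        if len(consistent) == 1:
            origins[ind.iid] = consistent.pop()
            continue
        origins[ind.iid] = _resolve_by_str(fam, ind, t, linked_str, founder_str_allele)
    return origins


def _resolve_by_str(
    fam: FamilyGenotypes,
    child: Individual,
    t: int,
    linked_str: str | None,
    founder_str_allele: int | None = None,
) -> str:
    """Disambiguate origin via a linked STR by enumerating transmissions.

    Enumerates, for both parents, every pairing of target alleles with
    STR alleles (local phase) and every transmitted haplotype, assuming
    no recombination between the target and the linked locus; keeps
    configurations matching the child's observed target genotype and STR
    allele pair, and reports the origin only if all of them agree.
    """
    if linked_str is None:
        return "ambiguous"
    ms = fam.microsatellites
    try:
        f_str = ms[child.father][linked_str]
        m_str = ms[child.mother][linked_str]
        c_str = ms[child.iid][linked_str]
    except KeyError:
        return "ambiguous"
    f_t = _gt_to_alleles(int(fam.genotypes[child.father][t]))
    m_t = _gt_to_alleles(int(fam.genotypes[child.mother][t]))
    c_t = sorted(_gt_to_alleles(int(fam.genotypes[child.iid][t])))
    if f_t is None or m_t is None or c_t is None:
        return "ambiguous"

    def allowed(phase: tuple[tuple[int, int], tuple[int, int]], str_pair) -> bool:
        # founder-haplotype constraint: a het parent carrying the founder
        # repeat is assumed to carry variant and repeat in cis
        if founder_str_allele is None or founder_str_allele not in str_pair:
            return True
        if all(a != 1 for a, _ in phase) or all(a == 1 for a, _ in phase):
            return True  # parent hom at target: nothing to orient
        return (1, founder_str_allele) in phase

    found: set[str] = set()
    for f_phase in _phasings(f_t, f_str):
        if not allowed(f_phase, f_str):
            continue
        for m_phase in _phasings(m_t, m_str):
            if not allowed(m_phase, m_str):
                continue
            for fh in f_phase:  # transmitted paternal haplotype (target, str)
                for mh in m_phase:
                    if sorted((fh[0], mh[0])) != c_t:
                        continue
                    if sorted((fh[1], mh[1])) != sorted(c_str):
                        continue
                    if fh[0] == 1 and mh[0] == 1:
                        found.add("both")
                    elif fh[0] == 1:
                        found.add("paternal")
                    elif mh[0] == 1:
                        found.add("maternal")
    if len(found) == 1:
        return found.pop()
    return "ambiguous"


def _gt_to_alleles(gt: int) -> tuple[int, int] | None:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(gt)


def _phasings(target_alleles: tuple[int, int], str_alleles: tuple[int, int]):
    """Distinct pairings of target alleles with STR alleles on two haplotypes."""
    seen = set()
    for perm in permutations(str_alleles):
        phase = ((target_alleles[0], perm[0]), (target_alleles[1], perm[1]))
        key = frozenset(phase)
        if key not in seen:
            seen.add(key)
            yield phase


def cosegregation_check(
    fam: FamilyGenotypes,
    ped: Pedigree,
    markers: MarkerSet,
    founder_str_alleles: dict[str, int] | None = None,
) -> SegregationReport:
    """Test whether founder markers travel with the variant in a family.

    An informative meiosis is a parent heterozygous at the target with a
    genotyped child.  For each, the variant's transmission is deduced
    from the child's and the other parent's genotypes; the child's marker
    content (alt present at every marker SNV, founder repeat count at
    every typed microsatellite) is compared against it.  ``cosegregates``
    is True iff every resolvable informative meiosis is concordant; with
    zero informative meioses it is None, flagged in the notes.

    ``founder_str_alleles`` names the repeat count riding on the founder
    haplotype per locus; when omitted, microsatellites are not scored.
    A one-step repeat mismatch is noted as a possible stepwise mutation
    and still counts as marker transmission.
    """
    t = fam.site_index(markers.target)
    marker_idx = [fam.site_index(m) for m in markers.markers]

    notes: list[str] = []
    mendelian_errors: list[str] = []
    meioses: list[dict] = []

    for parent in ped.individuals.values():
        if parent.iid not in fam.genotypes:
            continue
        if parent.carrier_status is None and int(fam.genotypes[parent.iid][t]) == MISSING:
            continue  # unknown status: skipped, not inferred
        if int(fam.genotypes[parent.iid][t]) != 1:
            continue
        for child in ped.children_of(parent.iid):
            if child.iid not in fam.genotypes:
                continue
            child_gt = int(fam.genotypes[child.iid][t])
            if child_gt == MISSING:
                continue
            other = child.mother if child.father == parent.iid else child.father
            other_gt = (
                int(fam.genotypes[other][t]) if other in fam.genotypes else MISSING
            )
            record: dict = {"parent": parent.iid, "child": child.iid}
            transmitted = _variant_transmitted(child_gt, other_gt)
            if transmitted is None:
                record["variant_transmitted"] = None
                record["resolved"] = False
                meioses.append(record)
                continue
            if child_gt == 2 and other_gt == 0:
                mendelian_errors.append(
                    f"{child.iid}: homozygous at {markers.target.chrom}:{markers.target.pos} "
                    f"with non-carrier parent {other}"
                )
            markers_present, step_notes = _marker_content(
                fam, child.iid, marker_idx, founder_str_alleles
            )
            notes.extend(step_notes)
            record.update(
                variant_transmitted=transmitted,
                markers_present=markers_present,
                concordant=(transmitted == markers_present),
                resolved=True,
            )
            meioses.append(record)

    n_informative = len(meioses)
    resolved = [m for m in meioses if m.get("resolved")]
    if n_informative == 0:
        notes.append("no informative meioses: co-segregation undefined")
        coseg: bool | None = None
    else:
        coseg = all(m["concordant"] for m in resolved) if resolved else None
    return SegregationReport(
        cosegregates=coseg,
        n_informative_meioses=n_informative,
        meioses=meioses,
        mendelian_errors=mendelian_errors,
        notes=notes,
    )


def _variant_transmitted(child_gt: int, other_parent_gt: int) -> bool | None:
    """Whether the focal het parent transmitted the alt allele; None if unresolvable."""
    if child_gt == 0:
        return False
    if child_gt == 2:
        return True
    # child het: attribute the single alt if the other parent cannot / must supply it
    if other_parent_gt == 0:
        return True
    if other_parent_gt == 2:
        return False
    return None  # other parent het or ungenotyped


def _marker_content(
    fam: FamilyGenotypes,
    iid: str,
    marker_idx: list[int],
    founder_str_alleles: dict[str, int] | None,
) -> tuple[bool, list[str]]:
    """Does this individual carry the full founder marker content?"""
    g = fam.genotypes[iid]
    snvs_ok = all(int(g[j]) >= 1 for j in marker_idx)
    step_notes: list[str] = []
    strs_ok = True
    if founder_str_alleles:
        for locus, founder_allele in founder_str_alleles.items():
            alleles = fam.microsatellites.get(iid, {}).get(locus)
            if alleles is None:
                continue
            if founder_allele in alleles:
                continue
            if min(abs(a - founder_allele) for a in alleles) == 1:
                step_notes.append(
                    f"{iid} {locus}: one-step repeat mismatch — possible stepwise mutation"
                )
            else:
                strs_ok = False
    return snvs_ok and strs_ok, step_notes
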