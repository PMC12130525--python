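"""Forward-time founder-population and assay simulators with known truth.

Everything the pipeline consumes can be generated here: a randomly
mating diploid population seeded with a single copy of a founder
haplotype (the target variant plus rare marker SNVs in cis), eroded by
Poisson-crossover recombination over g generations; family pedigrees
with stepwise-mutating microsatellites; telomerase direct-assay gel
lanes from a geometric per-repeat dissociation process; and an
age-declining control telomere-length reference.  Each simulator records
its ground truth (descent intervals, planted markers, true dissociation
probability, true age trend) so downstream modules can be tested by
parameter recovery.

Model choices: crossover counts per meiosis are Poisson with mean equal
to the genetic length of the region (no interference), positions i.i.d.
uniform — so the one-sided genetic length of founder material retained
around the target after g meioses is exponential with rate g, clipped at
the region edge.  Background haplotypes are mosaics of a small founder
panel (switch rate equal to the recombination rate), which produces
realistic incidental allele sharing; background variation is common
(annotated MAF >= 1%) while only the planted in-cis markers are rare, so
the rare-marker filter has an exact truth to recover.  Conditioning on
the target allele surviving to the final generation is by whole-run
rejection, never biased transmission, which preserves the neutral
erosion law.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, GenotypePanel, PhasedPanel, VariantSite
from .segregation import FamilyGenotypes, Individual, Pedigree
from .telomerase_quant import GelLane
from .telomere_percentiles import TLRecord

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-population simulation."""

    region_length: int = 10_000_000  # bp
    n_sites: int = 400
    target_index: int = 200
    n_marker_snvs: int = 6
    generations: int = 10
    pop_size: int = 200  # diploid N
    recomb_rate: float = 1e-8  # Morgans per bp per meiosis (~1 cM/Mb)
    marker_af_range: tuple[float, float] = (1e-4, 5e-3)
    min_final_carriers: int = 3
    seed: int = 0
    # layout / background structure
    chrom: str = "chr5"
    marker_span_bp: int = 500_000  # markers placed within this span around the target
    target_af: float = 6e-5
    background_panel_size: int = 20
    background_poly_fraction: float = 0.5
    background_af_range: tuple[float, float] = (0.01, 0.5)
    rejection_cap: int = 1000

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if not 0 <= self.target_index < self.n_sites:
            raise ValueError("target_index out of range")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 1 <= self.min_final_carriers <= 2 * self.pop_size:
            raise ValueError("min_final_carriers must be in [1, 2N]")
        if self.n_marker_snvs < 0 or self.n_marker_snvs >= self.n_sites - 1:
            raise ValueError("n_marker_snvs out of range")

    @property
    def genetic_length(self) -> float:
        """Region length in Morgans."""
        return self.recomb_rate * self.region_length


@dataclass
class TruthSet:
    """Ground truth of one simulated founder population."""

    founder_haplotype: np.ndarray  # allele vector over all sites
    target_pos: int
    target_index: int
    marker_indices: list[int]  # planted rare in-cis marker site indices
    carriers: list[tuple[str, int]]  # (sample id, haplotype index)
    descent_intervals: list[tuple[int, int]]  # bp, 1-based inclusive, per carrier
    generations: int
    region_length: int

    def __post_init__(self) -> None:
        for (s, e) in self.descent_intervals:
            if not (1 <= s <= self.target_pos <= e <= self.region_length):
                raise ValueError(
                    f"descent interval ({s}, {e}) violates target containment"
                )


class RejectionCapExceeded(RuntimeError):
    """The target allele was repeatedly lost before the final generation."""


# ---------------------------------------------------------------------------
# site layout and background panel


def _site_positions(config: SimConfig) -> np.ndarray:
    """Evenly spaced 1-based site positions across the region."""
    pos = np.round((np.arange(config.n_sites) + 0.5) * config.region_length / config.n_sites)
    return pos.astype(np.int64)


def _marker_site_indices(config: SimConfig, positions: np.ndarray) -> list[int]:
    """Site indices for the planted markers, spread around the target.

    Markers are placed symmetrically within ``marker_span_bp`` of the
    target (alternating sides), at the panel sites nearest the chosen
    offsets.
    """
    t = config.target_index
    tpos = positions[t]
    half = config.marker_span_bp / 2
    n = config.n_marker_snvs
    n_left = n // 2 + (n % 2)
    n_right = n // 2
    offsets = [-half * (k + 1) / max(n_left, 1) for k in range(n_left)]
    offsets += [half * (k + 1) / max(n_right, 1) for k in range(n_right)]
    chosen: list[int] = []
    for off in offsets:
        j = int(np.argmin(np.abs(positions - (tpos + off))))
        while j in chosen or j == t:
            j += 1 if off > 0 else -1
            if not 0 <= j < len(positions):
                raise ValueError("cannot place marker SNVs: panel too small for span")
        chosen.append(j)
    return sorted(chosen)


def _build_sites(
    config: SimConfig, marker_idx: list[int], rng: np.random.Generator
) -> tuple[list[VariantSite], np.ndarray]:
    """VariantSite list with AF annotations, plus the 20-haplotype background panel.

    Background polymorphic sites get a common AF annotation (the panel
    frequency); planted markers and the target get rare AFs and are alt
    only on the founder haplotype.
    """
    positions = _site_positions(config)
    K = config.background_panel_size
    S = config.n_sites
    panel = np.zeros((K, S), dtype=np.int8)
    af = np.zeros(S)
    special = set(marker_idx) | {config.target_index}
    for j in range(S):
        if j in special:
            continue
        if rng.random() < config.background_poly_fraction:
            m = int(rng.integers(1, K))  # alt copies among panel haplotypes
            panel[rng.choice(K, size=m, replace=False), j] = 1
            af[j] = m / K
    lo, hi = config.marker_af_range
    for j in marker_idx:
        af[j] = rng.uniform(lo, hi)
    af[config.target_index] = config.target_af

    bases = ["A", "C", "G", "T"]
    sites = []
    for j in range(S):
        ref, alt = rng.choice(4, size=2, replace=False)
        sid = "target_snv" if j == config.target_index else None
        sites.append(
            VariantSite(
                chrom=config.chrom,
                pos=int(positions[j]),
                ref=bases[ref],
                alt=bases[alt],
                global_af=float(af[j]),
                id=sid,
            )
        )
    return sites, panel


def _mosaic(
    panel: np.ndarray,
    positions: np.ndarray,
    genetic_length: float,
    region_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One background haplotype: a mosaic of the panel with Poisson switches."""
    K = panel.shape[0]
    k = rng.poisson(genetic_length)
    if k == 0:
        return panel[rng.integers(K)].copy()
    breaks = np.sort(rng.uniform(0, region_length, size=k))
    seg = np.searchsorted(breaks, positions)
    sources = rng.integers(K, size=k + 1)
    return panel[sources[seg], np.arange(panel.shape[1])].copy()


# ---------------------------------------------------------------------------
# meiosis

Interval = tuple[int, int]


def _intersect(intervals: list[Interval], lo: float, hi: float) -> list[Interval]:
    """Clip integer bp intervals to the real segment [lo, hi)."""
    out = []
    a = int(math.ceil(lo))
    b = int(math.ceil(hi)) - 1
    for (s, e) in intervals:
        ns, ne = max(s, a), min(e, b)
        if ns <= ne:
            out.append((ns, ne))
    return out


def _merge(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    desc_a: list[Interval],
    desc_b: list[Interval],
    positions: np.ndarray,
    genetic_length: float,
    region_length: int,
    rng: np.random.Generator,
    extra_a: np.ndarray | None = None,
    extra_b: np.ndarray | None = None,
    extra_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, list[Interval], np.ndarray | None]:
    """One recombinant gamete from a diploid parent.

    Crossover count ~ Poisson(genetic length), positions i.i.d. uniform;
    the gamete's founder-descent intervals are the parental intervals cut
    to the segments actually transmitted.  ``extra_*`` carries optional
    co-located integer alleles (microsatellite repeat counts) that travel
    with the segment containing their position.
    """
    k = rng.poisson(genetic_length)
    start = int(rng.integers(2))
    if k == 0:
        hap, desc = (hap_a, desc_a) if start == 0 else (hap_b, desc_b)
        extra = extra_a if start == 0 else extra_b
        return hap.copy(), list(desc), None if extra is None else extra.copy()
    breaks = np.sort(rng.uniform(0, region_length, size=k))
    seg = np.searchsorted(breaks, positions)
    from_a = (seg + start) % 2 == 0
    child = np.where(from_a, hap_a, hap_b)

    child_desc: list[Interval] = []
    edges = np.concatenate(([0.0], breaks, [float(region_length) + 1]))
    for i in range(k + 1):
        src_desc = desc_a if (i + start) % 2 == 0 else desc_b
        if src_desc:
            child_desc.extend(_intersect(src_desc, edges[i], edges[i + 1]))
    child_extra = None
    if extra_a is not None and extra_b is not None and extra_positions is not None:
        eseg = np.searchsorted(breaks, extra_positions)
        child_extra = np.where((eseg + start) % 2 == 0, extra_a, extra_b)
    return child.astype(np.int8), _merge(child_desc), child_extra


# ---------------------------------------------------------------------------
# founder-population simulation


def simulate_founder_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PhasedPanel, TruthSet]:
    """Forward-in-time simulation of a founder variant in a mating population.

    Generation 0 holds 2N background haplotypes with exactly one copy of
    the founder haplotype (alt at the target and at the planted marker
    sites).  Each later generation draws every offspring haplotype by
    recombining the two haplotypes of a random parent.  Whole runs are
    rejection-resampled until the final generation carries at least
    ``min_final_carriers`` copies of the target allele; the cap on
    attempts is explicit in the failure.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_idx = _marker_site_indices(config, _site_positions(config))
    sites, bg_panel = _build_sites(config, marker_idx, rng)
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    L = config.genetic_length
    N = config.pop_size

    founder = _mosaic(bg_panel, positions, L, config.region_length, rng)
    founder[marker_idx] = 1
    founder[config.target_index] = 1

    for _ in range(config.rejection_cap):
        haps = np.empty((2 * N, config.n_sites), dtype=np.int8)
        haps[0] = founder
        for h in range(1, 2 * N):
            haps[h] = _mosaic(bg_panel, positions, L, config.region_length, rng)
        descents: list[list[Interval]] = [[] for _ in range(2 * N)]
        descents[0] = [(1, config.region_length)]

        lost = False
        for _gen in range(config.generations):
            new_haps = np.empty_like(haps)
            new_desc: list[list[Interval]] = []
            parents = rng.integers(N, size=(N, 2))
            for i in range(N):
                for side in range(2):
                    p = int(parents[i, side])
                    g, d, _ = _gamete(
                        haps[2 * p],
                        haps[2 * p + 1],
                        descents[2 * p],
                        descents[2 * p + 1],
                        positions,
                        L,
                        config.region_length,
                        rng,
                    )
                    new_haps[2 * i + side] = g
                    new_desc.append(d)
            haps, descents = new_haps, new_desc
            if not np.any(haps[:, config.target_index] == 1):
                lost = True
                break
        if lost:
            continue
        n_carriers = int((haps[:, config.target_index] == 1).sum())
        if n_carriers >= config.min_final_carriers:
            break
    else:
        raise RejectionCapExceeded(
            f"target allele failed to reach {config.min_final_carriers} copies in "
            f"{config.rejection_cap} attempts"
        )

    samples = [f"S{i:04d}" for i in range(N)]
    panel = PhasedPanel(sites=sites, samples=samples, haplotypes=haps)
    carriers: list[tuple[str, int]] = []
    intervals: list[Interval] = []
    tpos = int(positions[config.target_index])
    for h in range(2 * N):
        if haps[h, config.target_index] == 1:
            carriers.append((samples[h // 2], h % 2))
            containing = [iv for iv in descents[h] if iv[0] <= tpos <= iv[1]]
            if not containing:
                raise AssertionError("carrier haplotype lacks founder descent at target")
            intervals.append(containing[0])
    truth = TruthSet(
        founder_haplotype=founder,
        target_pos=tpos,
        target_index=config.target_index,
        marker_indices=marker_idx,
        carriers=carriers,
        descent_intervals=intervals,
        generations=config.generations,
        region_length=config.region_length,
    )
    return panel, truth


def simulate_lineage_erosion(
    generations: int,
    recomb_rate: float,
    region_length: int,
    target_pos: int,
    n_lineages: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-segment erosion along single carrier lineages.

    Each lineage transmits the founder segment through ``generations``
    meioses; at each meiosis the retained interval is cut to the
    crossover segment containing the target.  Returns an array of shape
    ``(n_lineages, 2)`` with the left and right one-sided retained
    lengths in bp (multiply by ``recomb_rate`` for Morgans).
    """
    L = recomb_rate * region_length
    out = np.empty((n_lineages, 2))
    for i in range(n_lineages):
        lo, hi = 1.0, float(region_length)
        for _ in range(generations):
            k = rng.poisson(L)
            if k == 0:
                continue
            breaks = np.sort(rng.uniform(0, region_length, size=k))
            j = np.searchsorted(breaks, target_pos)
            seg_lo = breaks[j - 1] if j > 0 else 0.0
            seg_hi = breaks[j] if j < k else float(region_length)
            lo, hi = max(lo, seg_lo), min(hi, seg_hi)
        out[i, 0] = target_pos - lo
        out[i, 1] = hi - target_pos
    return out


def drop_phase(panel: PhasedPanel) -> GenotypePanel:
    """Collapse phased haplotypes to unordered per-site allele counts."""
    h0 = panel.haplotypes[0::2]
    h1 = panel.haplotypes[1::2]
    geno = (h0 + h1).astype(np.int8)
    geno[(h0 == MISSING) | (h1 == MISSING)] = MISSING
    return GenotypePanel(sites=list(panel.sites), samples=list(panel.samples), genotypes=geno)


def simulate_control_panel(
    sites: list[VariantSite],
    n_haplotypes: int,
    rng: np.random.Generator,
    af_override: dict[tuple[str, int, str, str], float] | None = None,
) -> PhasedPanel:
    """Non-founder control haplotypes with independent rare alleles.

    Each site's alt allele is drawn independently per haplotype at its
    annotated (or overridden) global AF — the null model in which
    carrying a multi-marker haplotype by chance is vanishingly rare.
    """
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (diploid samples)")
    afs = np.array(
        [
            af_override.get(s.key(), s.global_af) if af_override else s.global_af
            for s in sites
        ]
    )
    if np.any(np.isnan(afs)):
        raise ValueError("all sites need an AF to simulate controls")
    haps = (rng.random((n_haplotypes, len(sites))) < afs[None, :]).astype(np.int8)
    samples = [f"C{i:05d}" for i in range(n_haplotypes // 2)]
    return PhasedPanel(sites=list(sites), samples=samples, haplotypes=haps)


# ---------------------------------------------------------------------------
# pedigrees with microsatellites

STR_LOCI = ("D5S392", "D5S1981", "D5S2005", "D5S678")
STR_MUTATION_RATE = 1e-3  # per locus per meiosis, single-step

# Locus positions as fractions of the region; the D5S1981 stand-in sits
# right next to the target (inside the shared block).
_STR_POS_FRACTION = {"D5S392": 0.05, "D5S1981": 0.502, "D5S2005": 0.30, "D5S678": 0.85}


def simulate_families(
    config: SimConfig,
    rng: np.random.Generator,
    n_families: int = 3,
    n_children: int = 3,
) -> tuple[list[Pedigree], list[FamilyGenotypes], dict[str, int], list[VariantSite]]:
    """Nuclear families segregating the founder haplotype, with STRs.

    Each family has a heterozygous carrier parent (founder haplotype plus
    a background mosaic), a non-carrier spouse, and ``n_children``
    offspring produced by recombinant meioses.  Four microsatellite loci
    ride along with the haplotypes, mutating stepwise at 1e-3 per
    meiosis.  Returns pedigrees, family genotypes, the founder repeat
    count per STR locus, and the shared site list.
    """
    marker_idx = _marker_site_indices(config, _site_positions(config))
    sites, bg_panel = _build_sites(config, marker_idx, rng)
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    L = config.genetic_length

    founder = _mosaic(bg_panel, positions, L, config.region_length, rng)
    founder[marker_idx] = 1
    founder[config.target_index] = 1

    str_positions = np.array(
        [int(_STR_POS_FRACTION[l] * config.region_length) for l in STR_LOCI], dtype=np.int64
    )
    founder_strs = {l: int(rng.integers(10, 21)) for l in STR_LOCI}
    founder_str_vec = np.array([founder_strs[l] for l in STR_LOCI], dtype=np.int64)

    def background_strs() -> np.ndarray:
        # avoid colliding with the founder allele so the linked locus is informative
        vals = []
        for l in STR_LOCI:
            a = int(rng.integers(8, 25))
            while a == founder_strs[l]:
                a = int(rng.integers(8, 25))
            vals.append(a)
        return np.array(vals, dtype=np.int64)

    def mutate(strs: np.ndarray) -> np.ndarray:
        hit = rng.random(len(strs)) < STR_MUTATION_RATE
        steps = rng.choice([-1, 1], size=len(strs))
        return np.where(hit, np.maximum(strs + steps, 1), strs)

    pedigrees: list[Pedigree] = []
    families: list[FamilyGenotypes] = []
    for f in range(n_families):
        fid = f"FAM{f + 1}"
        father_id, mother_id = f"{fid}-P1", f"{fid}-P2"
        carrier_is_father = bool(rng.integers(2))
        # diploid parents: (haplotype vectors, STR vectors) x 2
        carrier = (
            (founder.copy(), founder_str_vec.copy()),
            (_mosaic(bg_panel, positions, L, config.region_length, rng), background_strs()),
        )
        spouse = tuple(
            (_mosaic(bg_panel, positions, L, config.region_length, rng), background_strs())
            for _ in range(2)
        )
        parents = {father_id: carrier if carrier_is_father else spouse,
                   mother_id: spouse if carrier_is_father else carrier}

        individuals: dict[str, Individual] = {}
        genotypes: dict[str, np.ndarray] = {}
        microsats: dict[str, dict[str, tuple[int, int]]] = {}

        for pid, sex in ((father_id, 1), (mother_id, 2)):
            (hA, sA), (hB, sB) = parents[pid]
            gt = (hA + hB).astype(np.int8)
            individuals[pid] = Individual(
                iid=pid, sex=sex, carrier_status=int(gt[config.target_index])
            )
            genotypes[pid] = gt
            microsats[pid] = {
                l: (int(sA[j]), int(sB[j])) for j, l in enumerate(STR_LOCI)
            }

        for c in range(n_children):
            cid = f"{fid}-C{c + 1}"
            child_haps, child_strs = [], []
            for pid in (father_id, mother_id):
                (hA, sA), (hB, sB) = parents[pid]
                g, _, strs = _gamete(
                    hA, hB, [], [], positions, L, config.region_length, rng,
                    extra_a=sA, extra_b=sB, extra_positions=str_positions,
                )
                child_haps.append(g)
                child_strs.append(mutate(strs))
            gt = (child_haps[0] + child_haps[1]).astype(np.int8)
            individuals[cid] = Individual(
                iid=cid,
                father=father_id,
                mother=mother_id,
                sex=int(rng.integers(1, 3)),
                carrier_status=int(gt[config.target_index]),
            )
            genotypes[cid] = gt
            microsats[cid] = {
                l: (int(child_strs[0][j]), int(child_strs[1][j]))
                for j, l in enumerate(STR_LOCI)
            }

        pedigrees.append(Pedigree(fid=fid, individuals=individuals))
        families.append(
            FamilyGenotypes(sites=sites, genotypes=genotypes, microsatellites=microsats)
        )
    return pedigrees, families, founder_strs, sites


# ---------------------------------------------------------------------------
# telomerase direct-assay lanes


@dataclass(frozen=True)
class AssayParams:
    """Parameters of the geometric band-intensity model for one lane.

    Intensity at repeat n is
    ``activity_scale * c(n) * d * (1 - d)**(n - 1) * (1 + eps_n)`` with
    multiplicative Gaussian noise; ``label_correction`` names c(n):
    "linear" (c(n) = n, label incorporation proportional to product
    length) or "uniform" (c(n) = 1).
    """

    dissociation_prob: float
    activity_scale: float = 1000.0
    n_repeats_max: int = 30
    label_correction: str = "linear"
    noise_sd: float = 0.0
    htr_recovered: float = 1.0
    htert_recovered: float = 1.0
    lysate_htr: float = 1.0
    lc: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dissociation_prob < 1.0:
            raise ValueError("dissociation_prob must be in (0, 1)")
        if self.n_repeats_max < 10:
            raise ValueError("n_repeats_max must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.label_correction not in ("linear", "uniform"):
            raise ValueError("label_correction must be 'linear' or 'uniform'")


def label_correction_fn(name: str):
    """Map a label-correction id to the c(n) callable."""
    return {"linear": lambda n: n, "uniform": lambda n: np.ones_like(n)}[name]


def simulate_gel_lane(
    params: AssayParams, rng: np.random.Generator | None = None, label: str = ""
) -> GelLane:
    """One direct-assay lane from the geometric dissociation model."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    d = params.dissociation_prob
    n = np.arange(1, params.n_repeats_max + 1, dtype=float)
    c = label_correction_fn(params.label_correction)(n)
    clean = params.activity_scale * c * d * (1.0 - d) ** (n - 1.0)
    noisy = clean * (1.0 + rng.normal(0.0, params.noise_sd, size=len(n)))
    return GelLane(
        intensities=np.clip(noisy, 0.0, None),
        lc=params.lc,
        ip_htr=params.htr_recovered,
        ip_htert=params.htert_recovered,
        lysate_htr=params.lysate_htr,
        label=label,
    )


def sample_product_lengths(
    dissociation_prob: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw product lengths (repeats added before dissociation); mean 1/d."""
    return rng.geometric(dissociation_prob, size=size)


# ---------------------------------------------------------------------------
# telomere-length reference


@dataclass(frozen=True)
class TLRefParams:
    """Linear age-decline model for a control telomere-length reference."""

    n_controls: int = 10_000
    age_range: tuple[float, float] = (40.0, 70.0)
    slope: float = -0.02  # measure units per year
    intercept: float = 1.0
    noise_sd: float = 0.5
    carrier_exclusion_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls <= 0:
            raise ValueError("n_controls must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be non-empty")
        if not 0.0 <= self.carrier_exclusion_fraction <= 1.0:
            raise ValueError("carrier_exclusion_fraction must be in [0, 1]")


def simulate_tl_reference(
    params: TLRefParams, rng: np.random.Generator | None = None
) -> list[TLRecord]:
    """Control telomere-length records declining linearly with age."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ages = rng.uniform(*params.age_range, size=params.n_controls)
    noise = rng.normal(0.0, params.noise_sd, size=params.n_controls) if params.noise_sd else np.zeros(params.n_controls)
    measures = params.intercept + params.slope * ages + noise
    carriers = rng.random(params.n_controls) < params.carrier_exclusion_fraction
    return [
        TLRecord(
            sample=f"CTL{i:05d}",
            age=float(ages[i]),
            measure=float(measures[i]),
            rare_variant_carrier=bool(carriers[i]),
        )
        for i in range(params.n_controls)
    ]


def simulate_tl_cases(
    params: TLRefParams,
    n_cases: int,
    rng: np.random.Generator,
    shift_sd: float = -2.0,
) -> list[TLRecord]:
    """Case records whose measures are shifted by ``shift_sd`` noise SDs."""
    ages = rng.uniform(*params.age_range, size=n_cases)
    measures = (
        params.intercept
        + params.slope * ages
        + shift_sd * params.noise_sd
        + rng.normal(0.0, params.noise_sd, size=n_cases)
    )
    return [
        TLRecord(sample=f"CASE{i:04d}", age=float(ages[i]), measure=float(measures[i]))
        for i in range(n_cases)
    ]
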