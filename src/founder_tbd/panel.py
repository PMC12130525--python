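"""Core genotype containers shared across the pipeline.

A :class:`PhasedPanel` holds ordered biallelic sites for a set of samples,
with two allele sequences per sample and phase known (the in-memory analog
of a phased multi-sample VCF).  A :class:`GenotypePanel` holds the same
sites as unordered per-sample allele counts.  Alleles are coded 0 (ref),
1 (alt), -1 (missing); genotypes 0/1/2, -1 missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV/indel site with optional global allele frequency."""

    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    global_af: float = math.nan
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if not math.isnan(self.global_af) and not 0.0 <= self.global_af <= 1.0:
            raise ValueError(f"global_af out of [0, 1]: {self.global_af}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PhasedPanel:
    """Ordered biallelic sites x samples with two phased allele rows per sample.

    ``haplotypes`` has shape ``(2 * n_samples, n_sites)``: rows ``2i`` and
    ``2i + 1`` are the two haplotypes of sample ``i``.  ``phased`` marks, per
    sample and site, whether the two alleles are truly ordered; sites flagged
    unphased still store both alleles but their order is arbitrary.
    """

    sites: list[VariantSite]
    samples: list[str]
    haplotypes: np.ndarray
    phased: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"haplotypes shape {self.haplotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        pos = self.positions
        if len(pos) > 1 and np.any(np.diff(pos) < 0):
            raise ValueError("sites must be sorted by position")
        if self.phased is not None:
            self.phased = np.asarray(self.phased, dtype=bool)
            if self.phased.shape != (len(self.samples), len(self.sites)):
                raise ValueError("phased mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chrom(self) -> str:
        return self.sites[0].chrom if self.sites else "."

    def is_phased(self, sample_idx: int, site_idx: int) -> bool:
        if self.phased is None:
            return True
        return bool(self.phased[sample_idx, site_idx])

    def sample_haplotypes(self, sample_idx: int) -> np.ndarray:
        return self.haplotypes[2 * sample_idx : 2 * sample_idx + 2]

    def find_site(self, site: VariantSite) -> int:
        """Index of ``site`` in the panel (matched on chrom, pos, ref, alt)."""
        for i, s in enumerate(self.sites):
            if s.key() == site.key():
                return i
        raise KeyError(f"site {site.chrom}:{site.pos}:{site.ref}>{site.alt} not in panel")

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alt allele frequency among non-missing alleles."""
        h = self.haplotypes
        called = h != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(called, h, 0).sum(axis=0) / called.sum(axis=0)


@dataclass
class GenotypePanel:
    """Unphased per-site allele counts (0/1/2, -1 missing) per sample."""

    sites: list[VariantSite]
    samples: list[str]
    genotypes: np.ndarray  # (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotypes shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def find_site(self, site: VariantSite) -> int:
        for i, s in enumerate(self.sites):
            if s.key() == site.key():
                return i
        raise KeyError(f"site {site.chrom}:{site.pos}:{site.ref}>{site.alt} not in panel")

    def allele_frequencies(self) -> np.ndarray:
        g = self.genotypes
        called = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(called, g, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
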