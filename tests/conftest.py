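import math

import numpy as np
import pytest

from founder_tbd import MarkerSet, PhasedPanel, VariantSite

BASES = ("A", "C", "G", "T")


def make_sites(positions, afs=None, chrom="chr5"):
    """Biallelic A>C test sites at the given positions."""
    afs = afs if afs is not None else [math.nan] * len(positions)
    return [
        VariantSite(chrom=chrom, pos=int(p), ref="A", alt="C", global_af=float(a))
        for p, a in zip(positions, afs)
    ]


def make_phased_panel(haplotypes, positions=None, afs=None, samples=None):
    """Panel from a (2*n_samples, n_sites) allele matrix."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n_sites = haplotypes.shape[1]
    if positions is None:
        positions = 100 * (np.arange(n_sites) + 1)
    if samples is None:
        samples = [f"S{i}" for i in range(haplotypes.shape[0] // 2)]
    return PhasedPanel(
        sites=make_sites(positions, afs), samples=samples, haplotypes=haplotypes
    )


def make_marker_set(sites, marker_indices, target_index):
    """MarkerSet over explicit site indices, flanks derived from position."""
    markers = [sites[j] for j in marker_indices]
    target = sites[target_index]
    left = [m for m in markers if m.pos < target.pos]
    right = [m for m in markers if m.pos > target.pos]
    return MarkerSet(
        markers=markers,
        marker_indices=list(marker_indices),
        target=target,
        target_index=target_index,
        left_flank=left[-1] if left else None,
        right_flank=right[0] if right else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def six_marker_panel():
    """9-site panel: target at index 4, six rare markers around it.

    Haplotype 0 is the founder haplotype (alt at target and all markers);
    the others are wild-type chromosomes.
    """
    positions = [100, 200, 300, 400, 500, 600, 700, 800, 900]
    afs = [0.20, 0.001, 0.004, 0.002, 6e-5, 0.003, 0.005, 0.0008, 0.30]
    founder = [0, 1, 1, 1, 1, 1, 1, 1, 0]
    wt = [0] * 9
    haps = np.array([founder, wt, wt, wt], dtype=np.int8)
    panel = make_phased_panel(haps, positions, afs, samples=["CARRIER", "CTRL"])
    markers = make_marker_set(panel.sites, [1, 2, 3, 5, 6, 7], target_index=4)
    return panel, markers
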