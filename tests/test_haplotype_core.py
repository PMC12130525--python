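"""Shared-block delimitation, marker filtering and span arithmetic."""

import math

import numpy as np
import pytest

from founder_tbd import (
    PhasedPanel,
    VariantSite,
    carrier_haplotypes,
    filter_rare_snvs,
    interval_span,
    shared_block,
)

from conftest import make_phased_panel, make_sites


def brute_force_block(carrier_matrix, positions, target_index):
    """Oracle: widest interval containing the target with full agreement.

    Enumerates every (i, j) with i <= target <= j and checks, pairwise,
    that all non-missing calls match at every site inside.
    """
    H = np.asarray(carrier_matrix)
    S = H.shape[1]

    def site_agrees(j):
        vals = H[:, j][H[:, j] >= 0]
        return len(vals) == 0 or np.all(vals == vals[0])

    best = (target_index, target_index)
    for i in range(target_index + 1):
        for j in range(target_index, S):
            if all(site_agrees(k) for k in range(i, j + 1)):
                if j - i > best[1] - best[0]:
                    best = (i, j)
    return positions[best[0]], positions[best[1]]


class TestCarrierHaplotypes:
    def target(self, panel):
        return panel.sites[1]

    def test_heterozygous_carriers_contribute_one_haplotype_each(self):
        # 3 het carriers + 1 non-carrier
        haps = np.array(
            [[0, 1, 0], [0, 0, 0],
             [0, 1, 0], [0, 0, 0],
             [0, 0, 0], [0, 1, 0],
             [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        panel = make_phased_panel(haps)
        carriers = carrier_haplotypes(panel, self.target(panel))
        assert len(carriers) == 3
        assert all(c.alleles[c.target_index] == 1 for c in carriers)

    def test_homozygous_carrier_contributes_both_haplotypes(self):
        haps = np.array(
            [[0, 1, 0], [0, 1, 0],   # homozygote
             [0, 1, 0], [0, 0, 0],
             [0, 1, 0], [0, 0, 0]], dtype=np.int8)
        panel = make_phased_panel(haps)
        assert len(carrier_haplotypes(panel, self.target(panel))) == 4

    def test_unphased_carrier_excluded_with_warning(self, caplog):
        haps = np.array(
            [[0, 1, 0], [0, 0, 0],
             [0, 1, 0], [0, 0, 0]], dtype=np.int8)
        phased = np.ones((2, 3), dtype=bool)
        phased[1, 1] = False
        panel = make_phased_panel(haps)
        panel.phased = phased
        with caplog.at_level("WARNING"):
            carriers = carrier_haplotypes(panel, self.target(panel))
        assert len(carriers) == 1
        assert any("unphased" in r.message for r in caplog.records)

    def test_target_absent_from_panel_fails(self):
        panel = make_phased_panel(np.zeros((2, 3), dtype=np.int8))
        missing = VariantSite(chrom="chr5", pos=9999, ref="G", alt="C")
        with pytest.raises(KeyError):
            carrier_haplotypes(panel, missing)


class TestSharedBlock:
    def test_single_carrier_spans_all_sites(self):
        haps = np.array([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]], dtype=np.int8)
        panel = make_phased_panel(haps)
        carriers = carrier_haplotypes(panel, panel.sites[2])
        block = shared_block(carriers, panel.sites)
        assert (block.start, block.end) == (100, 500)

    def test_disagreements_delimit_block(self):
        # positions 100..500, target at 300; B differs at 100, C at 500
        positions = [100, 200, 300, 400, 500]
        A = [0, 1, 1, 1, 0]
        B = [1, 1, 1, 1, 0]
        C = [0, 1, 1, 1, 1]
        haps = np.array([A, [0] * 5, B, [0] * 5, C, [0] * 5], dtype=np.int8)
        panel = make_phased_panel(haps, positions)
        carriers = carrier_haplotypes(panel, panel.sites[2])
        block = shared_block(carriers, panel.sites)
        assert (block.start, block.end) == (200, 400)
        assert (block.start, block.end) == brute_force_block(
            np.array([A, B, C]), positions, 2
        )

    def test_missing_calls_are_non_informative(self):
        A = [0, 1, 1, 1, 1]
        B = [-1, 1, 1, 1, -1]
        haps = np.array([A, [0] * 5, B, [0] * 5], dtype=np.int8)
        panel = make_phased_panel(haps)
        carriers = carrier_haplotypes(panel, panel.sites[2])
        block = shared_block(carriers, panel.sites)
        assert (block.start, block.end) == (100, 500)

    def test_empty_carrier_list_fails(self):
        panel = make_phased_panel(np.zeros((2, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            shared_block([], panel.sites)

    def test_matches_brute_force_on_random_panels(self, rng):
        """Oracle equivalence on random small panels."""
        for _ in range(300):
            S = int(rng.integers(3, 30))
            C = int(rng.integers(1, 8))
            t = int(rng.integers(S))
            H = rng.choice([0, 1, -1], size=(C, S), p=[0.55, 0.35, 0.10]).astype(np.int8)
            H[:, t] = 1
            positions = np.sort(rng.choice(np.arange(1, 100000), size=S, replace=False))
            rows = np.zeros((2 * C, S), dtype=np.int8)
            rows[0::2] = H
            panel = make_phased_panel(rows, positions)
            carriers = carrier_haplotypes(panel, panel.sites[t])
            block = shared_block(carriers, panel.sites)
            assert (block.start, block.end) == brute_force_block(H, positions, t)
            assert block.start <= positions[t] <= block.end

    def test_adding_a_carrier_never_widens_the_block(self, rng):
        for _ in range(100):
            S, C, t = 20, 5, 10
            H = rng.integers(0, 2, size=(C + 1, S)).astype(np.int8)
            H[:, t] = 1
            positions = 10 * (np.arange(S) + 1)

            def block_of(mat):
                rows = np.zeros((2 * len(mat), S), dtype=np.int8)
                rows[0::2] = mat
                panel = make_phased_panel(rows, positions)
                return shared_block(carrier_haplotypes(panel, panel.sites[t]), panel.sites)

            small = block_of(H[:C])
            big = block_of(H)
            assert small.start <= big.start and big.end <= small.end


class TestFilterRareSnvs:
    def test_six_rare_markers_with_correct_flanks(self, six_marker_panel):
        panel, _ = six_marker_panel
        carriers = carrier_haplotypes(panel, panel.sites[4])
        block = shared_block(carriers, panel.sites)
        ms = filter_rare_snvs(block, panel.sites)
        assert [m.pos for m in ms.markers] == [200, 300, 400, 600, 700, 800]
        assert ms.left_flank.pos == 400 and ms.right_flank.pos == 600
        assert ms.flanks_defined

    def test_all_common_sites_yield_empty_flagged_set(self):
        haps = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.int8)
        panel = make_phased_panel(haps, afs=[0.3, 0.2, 0.5])
        carriers = carrier_haplotypes(panel, panel.sites[1])
        block = shared_block(carriers, panel.sites)
        ms = filter_rare_snvs(block, panel.sites)
        assert ms.markers == [] and not ms.flanks_defined

    def test_threshold_one_disables_the_filter(self, six_marker_panel):
        panel, _ = six_marker_panel
        carriers = carrier_haplotypes(panel, panel.sites[4])
        block = shared_block(carriers, panel.sites)
        ms = filter_rare_snvs(block, panel.sites, threshold=1.0)
        # every founder-alt site except the target comes back
        assert [m.pos for m in ms.markers] == [200, 300, 400, 600, 700, 800]

    def test_af_table_overrides_site_annotation(self, six_marker_panel):
        panel, _ = six_marker_panel
        carriers = carrier_haplotypes(panel, panel.sites[4])
        block = shared_block(carriers, panel.sites)
        override = {panel.sites[1].key(): 0.5}  # pos 200 now common
        ms = filter_rare_snvs(block, panel.sites, af_table=override)
        assert [m.pos for m in ms.markers] == [300, 400, 600, 700, 800]

    def test_missing_af_treated_as_common_with_warning(self, caplog):
        haps = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.int8)
        panel = make_phased_panel(haps, afs=[0.001, 6e-5, math.nan])
        carriers = carrier_haplotypes(panel, panel.sites[1])
        block = shared_block(carriers, panel.sites)
        with caplog.at_level("WARNING"):
            ms = filter_rare_snvs(block, panel.sites)
        assert [m.pos for m in ms.markers] == [100]
        assert any("no AF annotation" in r.message for r in caplog.records)


class TestIntervalSpan:
    def test_reported_block_span(self):
        assert interval_span(776805, 1274733) == 497929

    @pytest.mark.parametrize("start,end,span", [(5, 5, 1), (1, 10, 10)])
    def test_inclusive_convention(self, start, end, span):
        assert interval_span(start, end) == span

    def test_reversed_interval_fails(self):
        with pytest.raises(ValueError):
            interval_span(10, 1)
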