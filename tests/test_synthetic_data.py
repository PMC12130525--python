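"""Simulator ground truth, erosion law, gel and telomere generators."""

import numpy as np
import pytest

from founder_tbd import (
    AssayParams,
    SimConfig,
    TLRefParams,
    drop_phase,
    sample_product_lengths,
    simulate_control_panel,
    simulate_families,
    simulate_founder_population,
    simulate_gel_lane,
    simulate_lineage_erosion,
    simulate_tl_reference,
)

SMALL = dict(n_sites=120, target_index=60, pop_size=60, generations=4,
             min_final_carriers=2)


class TestFounderPopulation:
    def test_zero_recombination_transmits_founder_intact(self):
        cfg = SimConfig(**SMALL, recomb_rate=0.0, seed=7)
        panel, truth = simulate_founder_population(cfg)
        assert truth.descent_intervals and all(
            iv == (1, cfg.region_length) for iv in truth.descent_intervals
        )
        for (sample, hap), _ in zip(truth.carriers, truth.descent_intervals):
            i = panel.samples.index(sample)
            np.testing.assert_array_equal(
                panel.haplotypes[2 * i + hap], truth.founder_haplotype
            )

    def test_single_generation_carriers_match_founder_within_descent(self):
        cfg = SimConfig(**{**SMALL, "generations": 1}, seed=3)
        panel, truth = simulate_founder_population(cfg)
        positions = panel.positions
        for (sample, hap), (lo, hi) in zip(truth.carriers, truth.descent_intervals):
            i = panel.samples.index(sample)
            inside = (positions >= lo) & (positions <= hi)
            np.testing.assert_array_equal(
                panel.haplotypes[2 * i + hap][inside], truth.founder_haplotype[inside]
            )

    def test_descent_intervals_contain_target(self):
        cfg = SimConfig(**SMALL, seed=11)
        _, truth = simulate_founder_population(cfg)
        assert all(lo <= truth.target_pos <= hi for lo, hi in truth.descent_intervals)

    def test_min_final_carriers_respected(self):
        cfg = SimConfig(**SMALL, seed=5)
        _, truth = simulate_founder_population(cfg)
        assert len(truth.carriers) >= cfg.min_final_carriers

    def test_identical_seeds_reproduce_and_seeds_differ(self):
        cfg = SimConfig(**SMALL, seed=9)
        p1, _ = simulate_founder_population(cfg)
        p2, _ = simulate_founder_population(cfg)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        p3, _ = simulate_founder_population(SimConfig(**SMALL, seed=10))
        assert not np.array_equal(p1.haplotypes, p3.haplotypes)

    def test_rejection_cap_failure_is_explicit(self):
        from founder_tbd import RejectionCapExceeded

        # demanding nearly-fixed allele after many generations cannot succeed
        cfg = SimConfig(**{**SMALL, "min_final_carriers": 2 * SMALL["pop_size"],
                           "rejection_cap": 3}, seed=1)
        with pytest.raises(RejectionCapExceeded, match="3 attempts"):
            simulate_founder_population(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=10, target_index=10)
        with pytest.raises(ValueError):
            SimConfig(recomb_rate=-1e-9)


class TestErosionLaw:
    def test_one_sided_length_matches_exponential_oracle(self, rng):
        """Mean one-sided retained genetic length ~ (1 - e^(-gD))/g Morgans.

        Closed form for the minimum of g i.i.d. exponential crossover
        distances, censored at the region edge (distance D Morgans).
        """
        g, r, L = 20, 1e-7, 10_000_000  # region = 1 Morgan, target centered
        target = L // 2
        lengths = simulate_lineage_erosion(g, r, L, target, 600, rng)
        mean_morgans = float(lengths.mean()) * r
        edge = r * target
        expected = (1.0 - np.exp(-g * edge)) / g
        assert abs(mean_morgans - expected) / expected < 0.10

    def test_two_sided_is_sum_of_one_sided(self, rng):
        g, r, L = 10, 1e-7, 10_000_000
        lengths = simulate_lineage_erosion(g, r, L, L // 2, 400, rng)
        total = lengths.sum(axis=1)
        assert np.all(total >= 0) and np.all(total <= L)
        expected = 2 * (1.0 - np.exp(-g * r * L / 2)) / g
        assert abs(total.mean() * r - expected) / expected < 0.15


class TestDropPhase:
    def test_genotype_values_and_af_preserved(self):
        cfg = SimConfig(**SMALL, seed=2)
        panel, _ = simulate_founder_population(cfg)
        geno = drop_phase(panel)
        h = panel.haplotypes
        np.testing.assert_array_equal(
            geno.genotypes, (h[0::2] + h[1::2]).astype(np.int8)
        )
        np.testing.assert_allclose(
            geno.allele_frequencies(), panel.allele_frequencies()
        )

    def test_het_and_hom_collapse(self):
        from conftest import make_phased_panel

        panel = make_phased_panel(np.array([[0, 1], [1, 1]], dtype=np.int8))
        geno = drop_phase(panel)
        np.testing.assert_array_equal(geno.genotypes[0], [1, 2])


class TestGelLane:
    def test_noiseless_intensity_ratio_closed_form(self):
        lane = simulate_gel_lane(AssayParams(dissociation_prob=0.5, noise_sd=0.0))
        # c(n)=n, d=0.5: I(2)/I(1) = 2*(1-d) = 1.0
        assert lane.intensities[1] / lane.intensities[0] == pytest.approx(1.0)

    def test_noiseless_log_decay_is_linear(self):
        d = 0.3
        lane = simulate_gel_lane(AssayParams(dissociation_prob=d, noise_sd=0.0))
        n = np.arange(1, lane.n_max + 1)
        y = np.log(lane.intensities / n)
        slopes = np.diff(y)
        np.testing.assert_allclose(slopes, np.log(1 - d), rtol=1e-12)

    def test_sampled_product_lengths_mean_is_inverse_d(self, rng):
        lengths = sample_product_lengths(0.25, 10_000, rng)
        assert abs(lengths.mean() - 4.0) < 0.15

    def test_metadata_copied_through(self):
        params = AssayParams(dissociation_prob=0.2, htr_recovered=2.0,
                             htert_recovered=3.0, lysate_htr=4.0, lc=50.0)
        lane = simulate_gel_lane(params)
        assert (lane.ip_htr, lane.ip_htert, lane.lysate_htr, lane.lc) == (2.0, 3.0, 4.0, 50.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AssayParams(dissociation_prob=1.5)
        with pytest.raises(ValueError):
            AssayParams(dissociation_prob=0.5, n_repeats_max=5)


class TestTLReference:
    def test_noiseless_measure_declines_with_age(self):
        records = simulate_tl_reference(
            TLRefParams(n_controls=200, noise_sd=0.0, slope=-0.02, seed=4)
        )
        by_age = sorted(records, key=lambda r: r.age)
        measures = [r.measure for r in by_age]
        assert all(a > b for a, b in zip(measures, measures[1:]))

    def test_zero_exclusion_fraction_flags_nobody(self):
        records = simulate_tl_reference(
            TLRefParams(n_controls=100, carrier_exclusion_fraction=0.0, seed=1)
        )
        assert not any(r.rare_variant_carrier for r in records)

    def test_fixed_seed_reproduces_table(self):
        from founder_tbd.io import tl_records_to_df

        p = TLRefParams(n_controls=50, seed=8)
        df1 = tl_records_to_df(simulate_tl_reference(p))
        df2 = tl_records_to_df(simulate_tl_reference(p))
        assert df1.to_csv(index=False) == df2.to_csv(index=False)


class TestControlPanel:
    def test_alt_frequency_close_to_annotated(self, rng):
        cfg = SimConfig(**SMALL, seed=6)
        panel, truth = simulate_founder_population(cfg)
        ctl = simulate_control_panel(panel.sites, 4000, rng)
        afs = np.array([s.global_af for s in ctl.sites])
        obs = ctl.allele_frequencies()
        # rare marker sites stay rare in controls
        for j in truth.marker_indices:
            assert obs[j] <= afs[j] + 0.01

    def test_odd_haplotype_count_rejected(self, rng):
        cfg = SimConfig(**SMALL, seed=6)
        panel, _ = simulate_founder_population(cfg)
        with pytest.raises(ValueError):
            simulate_control_panel(panel.sites, 7, rng)


class TestFamilies:
    def test_each_family_has_a_het_carrier_parent(self, rng):
        cfg = SimConfig(**SMALL, seed=12)
        peds, fams, founder_strs, sites = simulate_families(cfg, rng)
        assert len(peds) == 3
        for ped, fam in zip(peds, fams):
            parents = [i for i in ped.individuals.values()
                       if i.father == "0" and i.mother == "0"]
            carrier_parents = [p for p in parents if p.carrier_status == 1]
            assert len(carrier_parents) == 1
            t = cfg.target_index
            assert int(fam.genotypes[carrier_parents[0].iid][t]) == 1

    def test_str_repeat_counts_positive_at_four_loci(self, rng):
        cfg = SimConfig(**SMALL, seed=12)
        _, fams, founder_strs, _ = simulate_families(cfg, rng)
        assert set(founder_strs) == {"D5S392", "D5S1981", "D5S2005", "D5S678"}
        for fam in fams:
            for loci in fam.microsatellites.values():
                assert set(loci) == set(founder_strs)
                assert all(a >= 1 and b >= 1 for a, b in loci.values())
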