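"""The cohort generator: truth resolution, noise model, bulk VAFs, phasing."""

import numpy as np
import pytest

from mmescape import synthetic_cohort as sc
from mmescape.genomic_core import GenomicInterval, LocusDef, bins_overlapping
from conftest import two_clone_truth


class TestBuildTruth:
    def test_single_clone_no_events_is_diploid(self):
        truth = sc.build_truth(sc.preset_scenario("null-diploid"))
        assert (truth.profiles["diploid"] == 2).all()

    def test_child_events_stack_on_parent(self, mm2_truth):
        grid = mm2_truth.grid
        locus_bins = bins_overlapping(sc.TNFRSF17_LOCUS, grid)
        chr16 = grid.chrom_bin_ids("16")
        assert (mm2_truth.profiles["monosomy16"][chr16] == 1).all()
        assert (mm2_truth.profiles["biallelic"][locus_bins] == 0).all()
        # outside the focal event the child keeps the parent's monosomy
        other16 = [b for b in chr16 if b not in
                   bins_overlapping(LocusDef("f", sc._TNFRSF17_FOCAL), grid)]
        assert (mm2_truth.profiles["biallelic"][other16] == 1).all()

    def test_mm2_preset_resolves_three_profiles(self, mm2_truth):
        assert set(mm2_truth.clone_ids) == {"other", "monosomy16", "biallelic"}
        assert mm2_truth.fractions["pre"] == pytest.approx(
            {"other": 0.068, "monosomy16": 0.924, "biallelic": 0.008})
        assert mm2_truth.fractions["post"]["biallelic"] == pytest.approx(0.995)

    def test_mm31_preset_fractions(self, mm31_truth):
        post = mm31_truth.fractions["post"]
        assert [post[c] for c in ("nonsense", "missense", "bi_del", "translocation")] \
            == pytest.approx([0.45, 0.28, 0.12, 0.15])

    def test_cycle_detection(self):
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(
                sc.CloneSpec("a", "b", (), {"t": 0.5}),
                sc.CloneSpec("b", "a", (), {"t": 0.5}),
            ),
            n_cells={"t": 10}, bin_width=100,
        )
        with pytest.raises(ValueError, match="cycle"):
            sc.build_truth(cfg)

    def test_negative_cn_event_rejected(self):
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(
                sc.CloneSpec(
                    "a", "normal",
                    (sc.CNEventSpec(GenomicInterval("1", 1, 100), delta=-3),),
                    {"t": 1.0},
                ),
            ),
            n_cells={"t": 10}, bin_width=100,
        )
        with pytest.raises(ValueError, match="CN < 0"):
            sc.build_truth(cfg)

    def test_fractions_must_sum_to_one(self):
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(sc.CloneSpec("a", "normal", (), {"t": 0.9}),),
            n_cells={"t": 10}, bin_width=100,
        )
        with pytest.raises(ValueError, match="sum"):
            sc.build_truth(cfg)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            sc.preset_scenario("nope")


class TestSimulateCellMatrix:
    def test_noise_free_single_diploid_clone(self):
        truth = sc.build_truth(sc.noise_free(sc.preset_scenario("null-diploid")))
        m, labels = sc.simulate_cell_matrix(truth, "pre", seed=0)
        assert (m.cn == 2).all()
        assert set(labels) == {"diploid"}

    def test_noise_free_deletion_clone_exact(self):
        truth = two_clone_truth(n_cells=40, noise_free=True)
        m, labels = sc.simulate_cell_matrix(truth, "t", seed=1)
        del_bins = bins_overlapping(
            LocusDef("d", GenomicInterval("1", 200_001, 400_000)), truth.grid)
        for row, lab in zip(m.cn, labels):
            expected = 1 if lab == "B" else 2
            assert (row[del_bins] == expected).all()

    def test_determinism(self, mm2_truth):
        a, la = sc.simulate_cell_matrix(mm2_truth, "pre", seed=5)
        b, lb = sc.simulate_cell_matrix(mm2_truth, "pre", seed=5)
        assert a == b and la == lb

    def test_miscall_rate_matches_poisson_oracle(self):
        """At lambda=100, sigma=0.05 the per-bin CN mis-call rate on diploid
        bins matches the exact Poisson-tail computation (~1.5%) over 10^4
        bin observations, and stays below 2%."""
        from scipy import stats

        cfg = sc.CohortConfig(
            chrom_lengths={"1": 100 * 2000},
            clones=(sc.CloneSpec("a", "normal", (), {"t": 1.0}),),
            n_cells={"t": 100}, bin_width=2000,
            reads_per_bin=100.0, bias_sigma=0.05,
        )
        truth = sc.build_truth(cfg)
        m, _ = sc.simulate_cell_matrix(truth, "t", seed=0)
        assert m.cn.size == 10_000
        observed_rate = np.mean(m.cn != 2)
        # exact oracle: reads ~ Poisson(100 b); observed CN != 2 iff
        # rint(reads / (50 b)) != 2, i.e. reads < 1.5*50b or reads > 2.5*50b
        # (np.rint rounds halves to even, so both half-boundaries map to 2)
        rng = np.random.default_rng(99)
        bias = rng.lognormal(0.0, 0.05, size=20_000)
        p_ok = (stats.poisson.cdf(np.floor(125 * bias), 100 * bias)
                - stats.poisson.cdf(np.ceil(75 * bias) - 1, 100 * bias))
        expected_rate = float(np.mean(1 - p_ok))
        sigma = np.sqrt(expected_rate * (1 - expected_rate) / m.cn.size)
        assert abs(observed_rate - expected_rate) <= 4 * sigma
        assert observed_rate < 0.02

    def test_clone_fractions_converge(self, mm2_truth):
        """Law of large numbers: empirical fractions near spec at n=2000."""
        _, labels = sc.simulate_cell_matrix(mm2_truth, "pre", seed=11)
        n = len(labels)
        for clone, f in mm2_truth.fractions["pre"].items():
            sigma = np.sqrt(f * (1 - f) / n)
            assert abs(labels.count(clone) / n - f) <= 3 * sigma + 1e-12


class TestSimulateBulkVaf:
    def test_clonal_het_diploid_pure(self):
        truth = sc.build_truth(sc.preset_scenario("null-diploid"))
        v = sc.VariantSpec("v", "1", 500, "A", "T", {"diploid": 1})
        assert sc.expected_bulk_vaf(v, truth, "pre", purity=1.0) == pytest.approx(0.5)

    def test_purity_045_homozygous_gives_raw_045(self):
        """Clonal m=2 on CN 2 at purity 0.45: raw VAF 0.45 (whose correction
        is a corrected VAF of 100%)."""
        truth = sc.build_truth(sc.preset_scenario("null-diploid"))
        v = sc.VariantSpec("v", "1", 500, "A", "T", {"diploid": 2})
        assert sc.expected_bulk_vaf(v, truth, "pre", purity=0.45) == pytest.approx(0.45)

    def test_subclonal_half_fraction(self):
        truth = two_clone_truth()
        v = sc.VariantSpec("v", "1", 500_000, "A", "T", {"B": 1})
        assert sc.expected_bulk_vaf(v, truth, "t", purity=1.0) == pytest.approx(0.25)

    def test_read_sampling_seeded(self, mm31_truth):
        v = mm31_truth.variants[0]
        _, alt1, _ = sc.simulate_bulk_vaf(v, mm31_truth, "post", depth=200, seed=3)
        _, alt2, _ = sc.simulate_bulk_vaf(v, mm31_truth, "post", depth=200, seed=3)
        assert alt1 == alt2

    def test_bad_purity_rejected(self):
        truth = sc.build_truth(sc.preset_scenario("null-diploid"))
        v = sc.VariantSpec("v", "1", 500, "A", "T", {"diploid": 1})
        with pytest.raises(ValueError):
            sc.expected_bulk_vaf(v, truth, "pre", purity=0.0)


class TestSimulatePhasedPairs:
    @staticmethod
    def _disjoint_pair():
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(
                sc.CloneSpec("a", "normal", (), {"t": 0.5}),
                sc.CloneSpec("b", "normal", (), {"t": 0.5}),
            ),
            n_cells={"t": 10}, bin_width=100,
            variants=(
                sc.VariantSpec("v1", "1", 100, "A", "T", {"a": 1}),
                sc.VariantSpec("v2", "1", 150, "C", "G", {"b": 1}),
            ),
        )
        return sc.build_truth(cfg)

    def test_disjoint_clones_no_double_alt(self):
        truth = self._disjoint_pair()
        v1, v2 = truth.variants
        ev = sc.simulate_phased_pairs(v1, v2, truth, "t", 500, epsilon=0.0, seed=0)
        assert ev.n_aa == 0
        assert ev.n_ra > 0 and ev.n_ar > 0

    def test_same_haplotype_always_together(self):
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(sc.CloneSpec("a", "normal", (), {"t": 1.0}),),
            n_cells={"t": 10}, bin_width=100,
            variants=(
                sc.VariantSpec("v1", "1", 100, "A", "T", {"a": 1}),
                sc.VariantSpec("v2", "1", 150, "C", "G", {"a": 1}),
            ),
        )
        truth = sc.build_truth(cfg)
        v1, v2 = truth.variants
        ev = sc.simulate_phased_pairs(v1, v2, truth, "t", 500, epsilon=0.0, seed=0)
        assert ev.n_ra == 0 and ev.n_ar == 0
        assert ev.n_aa + ev.n_rr == 500

    def test_trans_configuration_never_together(self):
        cfg = sc.CohortConfig(
            chrom_lengths={"1": 1000},
            clones=(sc.CloneSpec("a", "normal", (), {"t": 1.0}),),
            n_cells={"t": 10}, bin_width=100,
            variants=(
                sc.VariantSpec("v1", "1", 100, "A", "T", {"a": 1}, copy_offset=0),
                sc.VariantSpec("v2", "1", 150, "C", "G", {"a": 1}, copy_offset=1),
            ),
        )
        truth = sc.build_truth(cfg)
        v1, v2 = truth.variants
        ev = sc.simulate_phased_pairs(v1, v2, truth, "t", 500, epsilon=0.0, seed=0)
        assert ev.n_aa == 0 and ev.n_rr == 0

    def test_error_driven_double_alt_matches_expectation(self):
        """With disjoint carriers, alt/alt pairs arise only from errors; the
        count matches the analytic expectation within 3 sigma."""
        truth = self._disjoint_pair()
        v1, v2 = truth.variants
        eps, n = 0.01, 10_000
        ev = sc.simulate_phased_pairs(v1, v2, truth, "t", n, epsilon=eps, seed=7)
        # haplotype carries v1 w.p. 1/4 and v2 w.p. 1/4, never both:
        # P(aa) = eps*(1-eps)*(1/4+1/4) + eps^2 * 1/2
        p_aa = eps * (1 - eps) * 0.5 + eps**2 * 0.5
        sigma = np.sqrt(n * p_aa * (1 - p_aa))
        assert abs(ev.n_aa - n * p_aa) <= 3 * sigma

    def test_bad_epsilon_rejected(self):
        truth = self._disjoint_pair()
        v1, v2 = truth.variants
        with pytest.raises(ValueError):
            sc.simulate_phased_pairs(v1, v2, truth, "t", 10, epsilon=0.7)
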