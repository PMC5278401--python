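"""The Queller-Goodnight estimator: worked values, algebraic reduction,
symmetry and ratio-of-sums semantics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_forced_dyad
from kinforce.forcing import DiploidGenotypes, DyadData, HaploidGenotypes, intersect_dyad
from kinforce.plink_io import AlleleFrequencyTable, Locus
from kinforce.rxy import rxy_forced, rxy_general


def _dyad(locus_defs, ax, ay):
    """Build a DyadData from (allele1, allele2, freq1) triples."""
    loci = [
        Locus(f"rs{i}", "1", 100 * (i + 1), a1, a2, f)
        for i, (a1, a2, f) in enumerate(locus_defs)
    ]
    return DyadData("x", "y", loci, list(ax), list(ay))


def _oracle_forced(loci, ax, ay):
    """Independent per-locus accumulation of (2d - pa - pc) / (2 - pa - pc)."""
    num = den = 0.0
    for loc, a, c in zip(loci, ax, ay):
        pa = loc.freq1 if a == loc.allele1 else 1 - loc.freq1
        pc = loc.freq1 if c == loc.allele1 else 1 - loc.freq1
        num += 2 * (a == c) - pa - pc
        den += 2 - pa - pc
    return num / den


class TestForced:
    def test_identical_alleles_give_one(self):
        d = _dyad([("A", "G", 0.2), ("C", "T", 0.45)], ["A", "C"], ["A", "C"])
        est = rxy_forced(d)
        assert est.value == pytest.approx(1.0)
        assert est.value == est.num_sum / est.den_sum

    def test_single_locus_mismatch_at_half_frequency(self):
        d = _dyad([("A", "G", 0.5)], ["A"], ["G"])
        est = rxy_forced(d)
        assert est.num_sum == pytest.approx(-1.0)
        assert est.den_sum == pytest.approx(1.0)
        assert est.value == pytest.approx(-1.0)

    def test_three_locus_worked_case_matches_hand_oracle(self):
        # shares alleles at loci 1 and 2, differs at locus 3;
        # the carried allele has p = 0.2, 0.5, 0.1 on both sides
        defs = [("A", "G", 0.2), ("C", "T", 0.5), ("G", "T", 0.1)]
        d = _dyad(defs, ["A", "C", "G"], ["A", "C", "T"])
        # hand: num = (2-0.4) + (2-1) + (0-0.1-0.9) = 1.6+1.0-1.0
        # den = (2-0.4) + (2-1) + (2-1.0) = 1.6+1.0+1.0
        assert rxy_forced(d).value == pytest.approx((1.6 + 1.0 - 1.0) / (1.6 + 1.0 + 1.0))
        assert rxy_forced(d).value == pytest.approx(_oracle_forced(d.loci, d.allele_x, d.allele_y))

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # per-locus ratios are 1 and -1 (mean 0); ratio of sums is not 0
        d = _dyad([("A", "G", 0.2), ("C", "T", 0.5)], ["A", "C"], ["A", "T"])
        est = rxy_forced(d)
        mean_of_ratios = np.mean([1.6 / 1.6, -1.0 / 1.0])
        assert est.value == pytest.approx(0.6 / 2.6)
        assert est.value != pytest.approx(mean_of_ratios)

    def test_value_not_clamped_below_zero(self):
        d = _dyad([("A", "G", 0.5)] * 3, ["A", "A", "A"], ["G", "G", "G"])
        assert rxy_forced(d).value < 0

    @given(st.integers(0, 10_000))
    def test_symmetry_and_locus_order_invariance(self, seed):
        panel, ax, ay = random_forced_dyad(seed, n_loci=30)
        loci = list(panel)
        d = DyadData("x", "y", loci, ax, ay)
        v = rxy_forced(d).value
        assert rxy_forced(d.swapped()).value == v
        perm = np.random.default_rng(seed).permutation(len(loci))
        d_perm = DyadData(
            "x", "y", [loci[i] for i in perm], [ax[i] for i in perm], [ay[i] for i in perm]
        )
        assert rxy_forced(d_perm).value == pytest.approx(v, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_per_locus_oracle_on_random_dyads(self, seed):
        panel, ax, ay = random_forced_dyad(seed, n_loci=25)
        d = DyadData("x", "y", list(panel), ax, ay)
        assert rxy_forced(d).value == pytest.approx(_oracle_forced(d.loci, ax, ay), rel=1e-12)


class TestGeneral:
    def test_double_heterozygote_locus_is_uninformative(self):
        panel = AlleleFrequencyTable(
            [Locus("rs1", "1", 100, "A", "G", 0.5), Locus("rs2", "1", 200, "A", "C", 0.2)]
        )
        gx = DiploidGenotypes("x", {"rs1": ("A", "G"), "rs2": ("A", "A")})
        gy = DiploidGenotypes("y", {"rs1": ("A", "G"), "rs2": ("A", "A")})
        est = rxy_general(gx, gy, panel)
        assert est.n_uninformative == 1
        assert est.value == pytest.approx(1.0)  # only the informative locus counts

    def test_symmetric_homozygote_mismatch(self):
        panel = AlleleFrequencyTable([Locus("rs1", "1", 100, "A", "G", 0.5)])
        gx = DiploidGenotypes("x", {"rs1": ("A", "A")})
        gy = DiploidGenotypes("y", {"rs1": ("G", "G")})
        assert rxy_general(gx, gy, panel).value == pytest.approx(-1.0)

    def test_hand_evaluated_mixed_locus(self):
        # x=(A,G), y=(A,A), p_A=0.2: num_x = 1-1 = 0, den_x = 0;
        # num_y = 1-0.4 = 0.6, den_y = 2-0.4 = 1.6 -> value 0.6/1.6
        panel = AlleleFrequencyTable([Locus("rs1", "1", 100, "A", "G", 0.2)])
        gx = DiploidGenotypes("x", {"rs1": ("A", "G")})
        gy = DiploidGenotypes("y", {"rs1": ("A", "A")})
        assert rxy_general(gx, gy, panel).value == pytest.approx(0.6 / 1.6)

    @given(st.integers(0, 10_000))
    def test_reduces_exactly_to_forced_on_duplicated_alleles(self, seed):
        """rxy_general on (a,a),(c,c) equals rxy_forced on a,c -- the algebraic
        reduction behind the forced-homozygote method."""
        panel, ax, ay = random_forced_dyad(seed, n_loci=40)
        gx = DiploidGenotypes("x", {loc.id: (a, a) for loc, a in zip(panel, ax)})
        gy = DiploidGenotypes("y", {loc.id: (c, c) for loc, c in zip(panel, ay)})
        forced = rxy_forced(DyadData("x", "y", list(panel), ax, ay))
        general = rxy_general(gx, gy, panel)
        assert general.value == pytest.approx(forced.value, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_general_symmetry(self, seed):
        from kinforce.simulate import simulate_dyad_diploid
        from kinforce.relatedness import RelatednessClass
        from kinforce.fixtures import generate_frequency_fixture

        panel = generate_frequency_fixture(30, seed=seed)
        rng = np.random.default_rng(seed)
        gx, gy = simulate_dyad_diploid(RelatednessClass.FIRST_ORDER, panel, rng)
        assert rxy_general(gx, gy, panel).value == rxy_general(gy, gx, panel).value


class TestPipelineConsistency:
    def test_self_dyad_value_is_one(self, rng):
        from kinforce.fixtures import generate_frequency_fixture
        from kinforce.forcing import force_diploid
        from kinforce.simulate import sample_unrelated

        panel = generate_frequency_fixture(100, seed=13)
        g = force_diploid(sample_unrelated(panel, rng), rng)
        d = intersect_dyad(g, HaploidGenotypes("copy", dict(g.alleles)), panel)
        assert rxy_forced(d).value == pytest.approx(1.0)

    def test_estimate_invariant_to_input_file_order(self, tmp_path):
        """Reading loci in a different file order leaves Rxy unchanged."""
        from kinforce.plink_io import read_frq, write_frq

        panel, ax, ay = random_forced_dyad(99, n_loci=20)
        gx = HaploidGenotypes("x", {loc.id: a for loc, a in zip(panel, ax)})
        gy = HaploidGenotypes("y", {loc.id: c for loc, c in zip(panel, ay)})
        v1 = rxy_forced(intersect_dyad(gx, gy, panel)).value
        reordered = AlleleFrequencyTable(list(panel)[::-1])
        v2 = rxy_forced(intersect_dyad(gx, gy, reordered)).value
        assert v1 == pytest.approx(v2, rel=1e-12)
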