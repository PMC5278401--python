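"""Forced-homozygote reduction and dyad intersection."""

import numpy as np
import pytest

from kinforce._rng import substream
from kinforce.errors import FormatError, NoSharedLociError
from kinforce.forcing import (
    DiploidGenotypes,
    HaploidGenotypes,
    force_dataset,
    force_diploid,
    force_site,
    haploid_to_dataset,
    intersect_dyad,
)
from kinforce.fixtures import generate_frequency_fixture
from kinforce.plink_io import AlleleFrequencyTable, Locus, PileupSiteCalls


class TestForceSite:
    def test_single_qualifying_read_is_deterministic(self):
        site = PileupSiteCalls("rs1", ("A",), (35,))
        assert force_site(site, min_qual=30) == "A"

    def test_no_qualifying_read_is_missing(self):
        site = PileupSiteCalls("rs1", ("A", "G"), (20, 25))
        assert force_site(site, min_qual=30) is None

    def test_empty_site_is_missing(self):
        assert force_site(PileupSiteCalls("rs1", (), ())) is None

    def test_threshold_is_inclusive(self):
        site = PileupSiteCalls("rs1", ("A",), (30,))
        assert force_site(site, min_qual=30) == "A"

    def test_uniform_choice_among_qualifying_reads(self, rng):
        site = PileupSiteCalls("rs1", ("A", "G"), (40, 40))
        n = 10_000
        picks = sum(force_site(site, 30, rng) == "A" for _ in range(n))
        sd = np.sqrt(n * 0.25)
        assert abs(picks - n / 2) < 3 * sd

    def test_low_quality_reads_never_selected(self, rng):
        site = PileupSiteCalls("rs1", ("A", "G", "G"), (40, 10, 12))
        assert all(force_site(site, 30, rng) == "A" for _ in range(50))


class TestForceDataset:
    def test_all_single_high_quality_reads_all_called(self):
        sites = [PileupSiteCalls(f"rs{i}", ("A",), (35,)) for i in range(10)]
        g = force_dataset(sites, "s", seed=1)
        assert len(g) == 10 and g.n_dropped == 0

    def test_all_low_quality_all_dropped(self):
        sites = [PileupSiteCalls(f"rs{i}", ("A",), (10,)) for i in range(7)]
        g = force_dataset(sites, "s", seed=1)
        assert len(g) == 0 and g.n_dropped == 7

    def test_drop_accounting(self):
        sites = [
            PileupSiteCalls("rs1", ("A",), (35,)),
            PileupSiteCalls("rs2", ("G",), (5,)),
            PileupSiteCalls("rs3", ("C", "T"), (31, 33)),
        ]
        g = force_dataset(sites, "s", seed=0)
        assert len(g) + g.n_dropped == len(sites)

    def test_duplicate_locus_rejected(self):
        sites = [PileupSiteCalls("rs1", ("A",), (35,))] * 2
        with pytest.raises(FormatError, match="duplicate"):
            force_dataset(sites, "s", seed=1)

    def test_per_site_substream_replay(self, rng):
        """Dataset-level forcing equals independent per-site replays and is
        invariant to site order."""
        sites = [
            PileupSiteCalls(f"rs{i}", ("A", "G", "C")[: 1 + i % 3], tuple([35] * (1 + i % 3)))
            for i in range(30)
        ]
        g = force_dataset(sites, "s", seed=11)
        for site in sites:
            replay = force_site(site, 30, rng=substream(11, "force_site", site.locus_id))
            assert g.alleles.get(site.locus_id) == replay
        g_rev = force_dataset(sites[::-1], "s", seed=11)
        assert g_rev.alleles == g.alleles


class TestForceDiploid:
    def test_homozygote_kept_deterministically(self, rng):
        g = DiploidGenotypes("s", {"rs1": ("A", "A")})
        assert all(
            force_diploid(g, np.random.default_rng(i)).alleles["rs1"] == "A"
            for i in range(20)
        )

    def test_heterozygote_kept_uniformly(self, rng):
        n = 10_000
        g = DiploidGenotypes("s", {"rs1": ("A", "G")})
        kept_a = sum(force_diploid(g, rng).alleles["rs1"] == "A" for _ in range(n))
        sd = np.sqrt(n * 0.25)
        assert abs(kept_a - n / 2) < 3 * sd

    def test_missing_call_dropped_and_counted(self, rng):
        g = DiploidGenotypes("s", {"rs1": ("0", "0"), "rs2": ("A", "0"), "rs3": ("C", "C")})
        forced = force_diploid(g, rng)
        assert forced.alleles == {"rs3": "C"}
        assert forced.n_dropped == 2

    def test_forcing_is_idempotent_on_duplicated_genotypes(self, rng):
        """Forcing an already-forced (duplicated-allele) individual is the identity."""
        g = DiploidGenotypes("s", {f"rs{i}": (b, b) for i, b in enumerate("ACGTAC")})
        forced = force_diploid(g, rng)
        duplicated = DiploidGenotypes("s", {k: (v, v) for k, v in forced.alleles.items()})
        again = force_diploid(duplicated, rng)
        assert again.alleles == forced.alleles

    def test_seeded_mode_is_order_independent(self):
        calls = {f"rs{i}": ("A", "G") for i in range(20)}
        g1 = DiploidGenotypes("s", calls)
        g2 = DiploidGenotypes("s", dict(reversed(list(calls.items()))))
        assert force_diploid(g1, seed=5).alleles == force_diploid(g2, seed=5).alleles

    def test_whole_individual_written_as_duplicated_pairs(self, tmp_path, rng):
        from kinforce.plink_io import write_dataset

        panel = generate_frequency_fixture(8, seed=2)
        g = DiploidGenotypes("s", {loc.id: (loc.allele1, loc.allele2) for loc in panel})
        forced = force_diploid(g, rng)
        ds = haploid_to_dataset([forced], list(panel))
        write_dataset(ds, tmp_path / "h.ped", tmp_path / "h.map")
        alleles = (tmp_path / "h.ped").read_text().split()[6:]
        for a, b in zip(alleles[::2], alleles[1::2]):
            assert a == b


class TestIntersectDyad:
    def test_plain_set_intersection(self, small_panel):
        gx = HaploidGenotypes("x", {"rs1": "A", "rs2": "C"})
        gy = HaploidGenotypes("y", {"rs2": "C", "rs3": "G"})
        d = intersect_dyad(gx, gy, small_panel)
        assert d.n_loci == 1 and d.loci[0].id == "rs2"

    def test_monomorphic_locus_excluded(self):
        panel = AlleleFrequencyTable([Locus("rs1", "1", 100, "A", "G", 1.0),
                                      Locus("rs2", "1", 200, "C", "T", 0.4)])
        gx = HaploidGenotypes("x", {"rs1": "A", "rs2": "C"})
        gy = HaploidGenotypes("y", {"rs1": "A", "rs2": "T"})
        d = intersect_dyad(gx, gy, panel)
        assert d.n_loci == 1 and d.exclusions["monomorphic"] == 1

    def test_allele_mismatch_excluded_not_recoded(self, small_panel):
        gx = HaploidGenotypes("x", {"rs1": "T", "rs2": "C"})  # T not in (A,G)
        gy = HaploidGenotypes("y", {"rs1": "A", "rs2": "C"})
        d = intersect_dyad(gx, gy, small_panel)
        assert d.n_loci == 1 and d.exclusions["allele_mismatch"] == 1

    def test_locus_without_frequency_counted(self, small_panel):
        gx = HaploidGenotypes("x", {"rs2": "C", "rsX": "A"})
        gy = HaploidGenotypes("y", {"rs2": "C", "rsX": "A"})
        d = intersect_dyad(gx, gy, small_panel)
        assert d.exclusions["no_frequency"] == 1

    def test_empty_intersection_is_an_error(self, small_panel):
        gx = HaploidGenotypes("x", {"rs1": "A"})
        gy = HaploidGenotypes("y", {"rs3": "G"})
        with pytest.raises(NoSharedLociError):
            intersect_dyad(gx, gy, small_panel)

    def test_symmetry_up_to_label_swap(self, small_panel):
        gx = HaploidGenotypes("x", {"rs1": "A", "rs2": "C", "rs4": "A"})
        gy = HaploidGenotypes("y", {"rs2": "T", "rs4": "A", "rs5": "T"})
        d_xy = intersect_dyad(gx, gy, small_panel)
        d_yx = intersect_dyad(gy, gx, small_panel)
        assert d_xy.allele_x == d_yx.allele_y and d_xy.allele_y == d_yx.allele_x
        assert [l.id for l in d_xy.loci] == [l.id for l in d_yx.loci]

    def test_planted_shared_loci_count(self):
        """The generator plants k usable shared loci; intersection recovers k."""
        panel = generate_frequency_fixture(40, seed=6)
        k = 17
        ids = panel.ids
        gx = HaploidGenotypes("x", {lid: panel[lid].allele1 for lid in ids[:30]})
        gy = HaploidGenotypes("y", {lid: panel[lid].allele2 for lid in ids[30 - k:]})
        d = intersect_dyad(gx, gy, panel)
        assert d.n_loci == k
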