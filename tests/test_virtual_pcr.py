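import numpy as np
import pytest

from kseq import (GenomeSequence, VpcrConfig, classify_products,
                  enumerate_products, find_binding_sites, run_virtual_pcr,
                  subset_report, summarize)
from kseq.virtual_pcr import BindingSite, PredictedProduct

from conftest import primers_from_genome, random_genome
from oracles import (brute_products, masked_count_prefix, rc,
                     regex_binding_sites)


def plain(seq, mask=None):
    m = np.zeros(len(seq), bool) if mask is None else np.asarray(mask, bool)
    return GenomeSequence({"c1": seq}, {"c1": m})


def site_tuples(sites):
    return {(s.chrom, s.start, s.strand, s.primer_id, s.mismatch_count,
             s.mismatch_positions) for s in sites}


class TestFindBindingSites:
    def test_exact_plus_match(self):
        sites = find_binding_sites(plain("AAAACGTACGTAAA"), "ACGTACGT", "p")
        # palindromic primer: the window matches on both strands
        assert {(s.start, s.strand) for s in sites} == {(3, "+"), (3, "-")}

    def test_minus_strand_site(self):
        # genome holds rc(primer) -> minus-strand site at the window start
        sites = find_binding_sites(plain("TTTTCCTTGG"), "CCAAGG", "p")
        assert {(s.start, s.strand) for s in sites} == {(4, "-")}

    def test_mismatch_positions_reported_in_primer_coords(self):
        sites = find_binding_sites(plain("AAAAAAAT"), "AAAAAAAA", "p",
                                   max_mismatches=1)
        plus = [s for s in sites if s.strand == "+" and s.start == 0]
        assert plus[0].mismatch_positions == (7,)

    def test_no_3prime_mismatch_mode(self):
        sites = find_binding_sites(plain("AAAAAAAT"), "AAAAAAAA", "p",
                                   max_mismatches=1,
                                   allow_3prime_mismatch=False)
        assert all(s.mismatch_count == 0 or 7 not in s.mismatch_positions
                   for s in sites)

    def test_n_window_never_a_site(self):
        sites = find_binding_sites(plain("AAAANAAA"), "AAAAAAAA", "p",
                                   max_mismatches=2)
        assert sites == []

    @pytest.mark.parametrize("mm", [0, 1])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_regex_variant_oracle(self, seed, mm):
        g = random_genome(seed, length=8_000, n_frac=0.003)
        pset = primers_from_genome(g, seed + 50, n_primers=4)
        for pid, primer in pset.primers().items():
            got = site_tuples(find_binding_sites(g, primer, pid, mm))
            assert got == regex_binding_sites(g, primer, pid, mm)


class TestEnumerateProducts:
    ROLES = {"F1": "forward", "R1": "reverse", "F2": "forward"}

    def test_planted_convergent_pair(self):
        sites = [BindingSite("c1", 100, "+", "F1", 8),
                 BindingSite("c1", 492, "-", "R1", 8)]
        prods = enumerate_products(sites, self.ROLES)
        assert len(prods) == 1
        p = prods[0]
        assert (p.start, p.end, p.length, p.in_size_window) == (100, 500, 400,
                                                                True)
        assert p.pair == ("F1", "R1")

    def test_forward_forward_excluded(self):
        sites = [BindingSite("c1", 100, "+", "F1", 8),
                 BindingSite("c1", 492, "-", "F2", 8)]
        assert enumerate_products(sites, self.ROLES) == []

    def test_overlapping_sites_excluded(self):
        sites = [BindingSite("c1", 100, "+", "F1", 8),
                 BindingSite("c1", 104, "-", "R1", 8)]
        assert enumerate_products(sites, self.ROLES) == []

    def test_reverse_forward_left_right_allowed(self):
        sites = [BindingSite("c1", 100, "+", "R1", 8),
                 BindingSite("c1", 492, "-", "F1", 8)]
        prods = enumerate_products(sites, self.ROLES)
        assert len(prods) == 1 and prods[0].pair == ("F1", "R1")

    def test_all_qualifying_pairs_emitted(self):
        sites = [BindingSite("c1", 0, "+", "F1", 8),
                 BindingSite("c1", 392, "-", "R1", 8),
                 BindingSite("c1", 592, "-", "R1", 8)]
        assert len(enumerate_products(sites, self.ROLES)) == 2

    def test_size_bounds_enforced(self):
        sites = [BindingSite("c1", 0, "+", "F1", 8),
                 BindingSite("c1", 20, "-", "R1", 8),     # span 28 < 50
                 BindingSite("c1", 2500, "-", "R1", 8)]   # span > 2000
        assert enumerate_products(sites, self.ROLES) == []


class TestClassify:
    def test_unmasked_product_single(self):
        g = plain("A" * 1000)
        p = PredictedProduct("c1", 0, 400, "F1", "forward", "R1", "reverse",
                             True)
        classify_products([p], g)
        assert p.classification == "single" and p.masked_base_fraction == 0.0

    def test_majority_masked_repetitive(self):
        mask = np.zeros(1000, bool)
        mask[0:240] = True  # 60% of a 400 bp product
        p = PredictedProduct("c1", 0, 400, "F1", "forward", "R1", "reverse",
                             True)
        classify_products([p], plain("A" * 1000, mask))
        assert p.classification == "repetitive"
        assert p.masked_base_fraction == pytest.approx(0.6)


class TestReports:
    def prods(self):
        mk = lambda s, e, f, r: PredictedProduct(
            "c1", s, e, f, "forward", r, "reverse", True,
            classification="single", masked_base_fraction=0.0)
        return [mk(0, 400, "F1", "R1"), mk(1000, 1400, "F1", "R1"),
                mk(2000, 2400, "F2", "R1")]

    ROLES = {"F1": "forward", "F2": "forward", "R1": "reverse"}

    def test_per_pair_rows_and_totals(self):
        rep = summarize(self.prods(), self.ROLES)
        rows = {(r.forward_id, r.reverse_id): r.n_products
                for r in rep.per_pair.itertuples()}
        assert rows == {("F1", "R1"): 2, ("F2", "R1"): 1}
        assert rep.totals["n_products"] == 3
        assert rep.per_pair.n_products.sum() == rep.totals["n_products"]

    def test_subset_report_filters_pairs(self):
        rep = subset_report(self.prods(), self.ROLES, {"F1", "R1"})
        assert rep.totals["n_products"] == 2

    def test_subset_without_reverse_is_empty(self, caplog):
        with caplog.at_level("WARNING", logger="kseq"):
            rep = subset_report(self.prods(), self.ROLES, {"F1", "F2"})
        assert rep.totals["n_products"] == 0 and len(rep.per_pair) == 0
        assert "lacks" in caplog.text


class TestPipelineProperties:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_full_pipeline_matches_brute_force(self, seed):
        g = random_genome(seed, length=10_000, mask_frac=0.2, n_frac=0.002)
        pset = primers_from_genome(g, seed + 10, n_primers=6)
        roles = pset.roles()
        config = VpcrConfig(max_mismatches=1)
        products, _ = run_virtual_pcr(g, pset, config)

        sites = set()
        for pid, primer in pset.primers().items():
            sites |= regex_binding_sites(g, primer, pid, 1)
        site_objs = [BindingSite(c, s, st, pid, len(primer := pset.primers()[pid]),
                                 mmc, mmp)
                     for c, s, st, pid, mmc, mmp in sites]
        expected = brute_products(site_objs, roles, config.min_product_len,
                                  config.max_product_len)
        got = {(p.chrom, p.start, p.end, p.left_id, p.right_id)
               for p in products}
        assert got == expected
        prefix = masked_count_prefix(g)
        for p in products:
            masked = prefix[p.chrom][p.end] - prefix[p.chrom][p.start]
            assert p.masked_base_fraction == masked / p.length
            assert p.classification == (
                "repetitive" if masked / p.length > 0.5 else "single")

    def test_mismatch_monotonicity(self):
        g = random_genome(6, length=10_000)
        pset = primers_from_genome(g, 16, n_primers=6)
        keysets = []
        for mm in (0, 1, 2):
            prods, _ = run_virtual_pcr(g, pset, VpcrConfig(max_mismatches=mm))
            keysets.append({(p.chrom, p.start, p.end, p.left_id, p.right_id)
                            for p in prods})
        assert keysets[0] <= keysets[1] <= keysets[2]

    def test_strand_symmetry(self):
        g = random_genome(8, length=10_000, mask_frac=0.1)
        pset = primers_from_genome(g, 18, n_primers=6)
        n = g.chrom_length("chr1")
        g_rc = GenomeSequence({"chr1": rc(g.sequences["chr1"])},
                              {"chr1": g.masks["chr1"][::-1].copy()})
        prods, rep = run_virtual_pcr(g, pset)
        prods_rc, rep_rc = run_virtual_pcr(g_rc, pset)
        mirrored = {(n - p.end, n - p.start, p.pair) for p in prods_rc}
        assert {(p.start, p.end, p.pair) for p in prods} == mirrored
        pairs = rep.per_pair.set_index(["forward_id", "reverse_id"])
        pairs_rc = rep_rc.per_pair.set_index(["forward_id", "reverse_id"])
        assert pairs.n_products.to_dict() == pairs_rc.n_products.to_dict()

    def test_no_product_violates_role_or_size_rules(self):
        for seed in (21, 22):
            g = random_genome(seed, length=10_000)
            pset = primers_from_genome(g, seed, n_primers=6)
            config = VpcrConfig(max_mismatches=1)
            prods, _ = run_virtual_pcr(g, pset, config)
            for p in prods:
                assert {p.left_role, p.right_role} == {"forward", "reverse"}
                assert config.min_product_len <= p.length <= config.max_product_len
                assert p.in_size_window == (300 <= p.length <= 700)


def test_products_bed_export(tmp_path):
    g = random_genome(30, length=10_000)
    pset = primers_from_genome(g, 31, n_primers=6)
    prods, _ = run_virtual_pcr(g, pset, VpcrConfig(max_mismatches=1))
    from kseq import products_to_bed, read_bed

    products_to_bed(prods, tmp_path / "p.bed")
    back = read_bed(tmp_path / "p.bed")
    assert back.regions == [(p.chrom, p.start, p.end) for p in prods]
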