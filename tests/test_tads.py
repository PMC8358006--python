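"""TAD/loop integration vs brute-force adjacency oracles."""

import logging

import numpy as np
import pytest

from silencerkit.core import ChromatinLoop, GeneModel, GenomicInterval, ValidationError
from silencerkit.domains import Domain
from silencerkit.tads import (
    assign_target_genes,
    interaction_connectivity,
    permutation_interaction_test,
    tad_overlap_summary,
    tad_position_profile,
    term_enrichment_correlation,
)


def _dom(chrom, start, end, did="D0", label="grand"):
    return Domain(GenomicInterval(chrom, start, end), end - start,
                  class_label=label, domain_id=did)


def _loop(c1, s1, e1, c2, s2, e2):
    return ChromatinLoop(GenomicInterval(c1, s1, e1),
                         GenomicInterval(c2, s2, e2))


def _overlap(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


def connectivity_oracle(domains, loops):
    """Brute-force adjacency: connected set and partner-anchor counts."""
    connected = set()
    partners = {}
    for d in domains:
        for loop in loops:
            for me, other in ((loop.anchor1, loop.anchor2),
                              (loop.anchor2, loop.anchor1)):
                if me.chrom == d.chrom and _overlap(d.start, d.end,
                                                    me.start, me.end):
                    partners.setdefault(d.domain_id, set()).add(
                        (other.chrom, other.start, other.end))
                    for d2 in domains:
                        if d2 is d:
                            continue
                        if other.chrom == d2.chrom and _overlap(
                                d2.start, d2.end, other.start, other.end):
                            connected.add(d.domain_id)
    return connected, {k: len(v) for k, v in partners.items()}


class TestTadOverlapSummary:
    def test_domain_spanning_tad(self):
        d = _dom("chr1", 0, 100_000)
        tads = [GenomicInterval("chr1", 10_000, 90_000)]
        rels = tad_overlap_summary({"grand": [d]}, tads, [])["grand"]
        assert rels[0].overlaps_tad
        assert rels[0].covered_fraction_of_tad == pytest.approx(1.0)
        assert rels[0].spans_entire_tad

    def test_distant_domain_all_flags_false(self):
        d = _dom("chr1", 0, 10)
        tads = [GenomicInterval("chr1", 500_000, 600_000)]
        rels = tad_overlap_summary({"grand": [d]}, tads, [])["grand"]
        assert not rels[0].overlaps_tad and not rels[0].spans_entire_tad
        assert not rels[0].marks_anchor

    def test_coverage_threshold_is_strict_geq(self):
        tads = [GenomicInterval("chr1", 0, 100_000)]
        at_89 = _dom("chr1", 0, 89_000)
        at_90 = _dom("chr1", 0, 90_000)
        rels = tad_overlap_summary({"grand": [at_89, at_90]}, tads, [],
                                   coverage_threshold=0.9)["grand"]
        assert not rels[0].spans_entire_tad
        assert rels[1].spans_entire_tad

    def test_anchor_marking(self):
        d = _dom("chr1", 0, 50_000)
        loops = [_loop("chr1", 40_000, 45_000, "chr1", 500_000, 505_000)]
        rels = tad_overlap_summary({"grand": [d]},
                                   [GenomicInterval("chr1", 0, 60_000)],
                                   loops)["grand"]
        assert rels[0].marks_anchor

    def test_overlapping_tads_rejected(self):
        tads = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 200)]
        with pytest.raises(ValidationError, match="overlapping TADs"):
            tad_overlap_summary({"grand": []}, tads, [])


class TestTadPositionProfile:
    def test_centered_domain_at_zero(self):
        tads = [GenomicInterval("chr1", 0, 100_000)]
        d = _dom("chr1", 40_000, 60_000)  # midpoint = TAD midpoint
        res = tad_position_profile({"grand": [d]}, tads, n_bins=10)
        density = np.array(res["classes"]["grand"]["density"])
        # all mass in one of the two central bins
        assert density[4] + density[5] == pytest.approx(density.sum())

    def test_boundary_domain_at_minus_one(self):
        tads = [GenomicInterval("chr1", 100_000, 200_000)]
        d = _dom("chr1", 95_000, 105_000)  # midpoint at TAD start
        res = tad_position_profile({"grand": [d]}, tads, n_bins=10)
        density = np.array(res["classes"]["grand"]["density"])
        assert density[0] == pytest.approx(density.sum())

    def test_no_tad_overlap_excluded_and_counted(self):
        tads = [GenomicInterval("chr1", 0, 1000)]
        d = _dom("chr1", 500_000, 510_000)
        res = tad_position_profile({"grand": [d]}, tads)
        assert res["classes"]["grand"]["n_excluded"] == 1
        assert res["classes"]["grand"]["n_domains"] == 0

    def test_uniform_random_mean_position_near_zero(self, rng):
        tads = [GenomicInterval("chr1", i * 100_000, (i + 1) * 100_000)
                for i in range(10)]
        domains = []
        for i in range(300):
            s = int(rng.integers(0, 999_000))
            domains.append(_dom("chr1", s, s + 1000, f"D{i}"))
        res = tad_position_profile({"grand": domains}, tads, n_bins=10)
        density = np.array(res["classes"]["grand"]["density"])
        centers = np.arange(-0.9, 1.0, 0.2)
        mean_pos = float((density * centers).sum() / density.sum())
        assert abs(mean_pos) < 0.15


class TestConnectivity:
    def test_two_domains_one_loop(self):
        a = _dom("chr1", 0, 10_000, "DA")
        b = _dom("chr1", 50_000, 60_000, "DB")
        loops = [_loop("chr1", 2000, 4000, "chr1", 52_000, 54_000)]
        res = interaction_connectivity({"grand": [a, b]}, loops)["grand"]
        assert res["n_connected"] == 2
        assert res["connected_fraction"] == 1.0
        assert res["multiplexity"] == {"1": 2, "2": 0, ">=3": 0}

    def test_self_loop_excluded(self):
        a = _dom("chr1", 0, 100_000, "DA")
        loops = [_loop("chr1", 1000, 2000, "chr1", 50_000, 51_000)]
        res = interaction_connectivity({"grand": [a]}, loops)["grand"]
        assert res["n_connected"] == 0

    def test_cross_class_loops_do_not_connect(self):
        a = _dom("chr1", 0, 10_000, "DA", "grand")
        b = _dom("chr1", 50_000, 60_000, "DB", "narrow")
        loops = [_loop("chr1", 2000, 4000, "chr1", 52_000, 54_000)]
        res = interaction_connectivity({"grand": [a], "narrow": [b]}, loops)
        assert res["grand"]["n_connected"] == 0
        assert res["narrow"]["n_connected"] == 0

    def test_random_toys_match_adjacency_oracle(self, rng):
        for _ in range(40):
            domains = []
            pos = 0
            for i in range(int(rng.integers(1, 12))):
                pos += int(rng.integers(100, 2000))
                w = int(rng.integers(500, 5000))
                domains.append(_dom("chr1", pos, pos + w, f"D{i}"))
                pos += w
            loops = []
            for _ in range(int(rng.integers(0, 15))):
                s1 = int(rng.integers(0, pos + 5000))
                s2 = int(rng.integers(0, pos + 5000))
                loops.append(_loop("chr1", s1, s1 + 400, "chr1", s2, s2 + 400))
            res = interaction_connectivity({"grand": domains}, loops)["grand"]
            oracle_connected, oracle_partners = connectivity_oracle(domains, loops)
            got_connected = {d.domain_id for d in domains
                            if d.domain_id in
                            [domains[i].domain_id for i in range(len(domains))]
                            } & oracle_connected
            assert res["n_connected"] == len(oracle_connected)
            assert res["partner_anchor_counts"] == oracle_partners


class TestPermutationTest:
    def test_no_loops_gives_p_one(self):
        d = _dom("chr1", 0, 10_000, "DA")
        res = permutation_interaction_test([d], [], {"chr1": 1_000_000},
                                           n_perm=100, seed=0)
        assert res.observed == 0
        assert res.p == 1.0

    def test_forced_extreme_hits_add_one_floor(self):
        # tiny domains on a huge chromosome, loops exactly on them:
        # no shuffle can reproduce the observed count
        doms = [_dom("chr1", i * 1_000_000, i * 1_000_000 + 200, f"D{i}")
                for i in range(4)]
        loops = [_loop("chr1", doms[i].start, doms[i].end,
                       "chr1", doms[i + 1].start, doms[i + 1].end)
                 for i in range(3)]
        res = permutation_interaction_test(doms, loops,
                                           {"chr1": 500_000_000},
                                           n_perm=100, seed=3)
        assert res.observed == 4
        assert res.p == pytest.approx(1 / 101)

    def test_seed_reproducibility(self):
        doms = [_dom("chr1", 0, 10_000, "DA"),
                _dom("chr1", 100_000, 130_000, "DB")]
        loops = [_loop("chr1", 1000, 2000, "chr1", 110_000, 111_000)]
        sizes = {"chr1": 1_000_000}
        r1 = permutation_interaction_test(doms, loops, sizes, 150, seed=9)
        r2 = permutation_interaction_test(doms, loops, sizes, 150, seed=9)
        assert r1.null_counts == r2.null_counts and r1.p == r2.p

    def test_domain_longer_than_chromosome_rejected(self):
        d = _dom("chr1", 0, 2_000_000, "DA")
        with pytest.raises(ValidationError):
            permutation_interaction_test([d], [], {"chr1": 1_000_000},
                                         n_perm=100)

    def test_min_permutations_enforced(self):
        d = _dom("chr1", 0, 100, "DA")
        with pytest.raises(ValueError):
            permutation_interaction_test([d], [], {"chr1": 1000}, n_perm=10)


class TestTargetGenes:
    def _setup(self):
        dom = _dom("chr1", 0, 60_000, "DA")
        # loop from inside the domain to a distal anchor [200k, 205k)
        loops = [_loop("chr1", 10_000, 15_000, "chr1", 200_000, 205_000)]
        return dom, loops

    def test_gene_within_distance_targeted(self):
        dom, loops = self._setup()
        gene = GeneModel("g1", "chr1", "+", 207_000, 215_000)  # 2 kb away
        res = assign_target_genes([dom], loops, [gene])
        assert res["targets"]["DA"] == ["g1"]

    def test_gene_at_exact_distance_targeted(self):
        dom, loops = self._setup()
        gene = GeneModel("g1", "chr1", "+", 208_000, 215_000)  # 3000 bp away
        res = assign_target_genes([dom], loops, [gene], distance=3000)
        assert res["targets"]["DA"] == ["g1"]

    def test_gene_beyond_distance_not_targeted(self):
        dom, loops = self._setup()
        gene = GeneModel("g1", "chr1", "+", 208_001, 215_000)  # 3001 bp away
        res = assign_target_genes([dom], loops, [gene], distance=3000)
        assert res["targets"]["DA"] == []

    def test_both_anchors_in_grand_domains_deduplicated(self):
        d1 = _dom("chr1", 0, 60_000, "DA")
        d2 = _dom("chr1", 200_000, 260_000, "DB")
        loops = [_loop("chr1", 10_000, 15_000, "chr1", 210_000, 215_000),
                 _loop("chr1", 10_000, 15_000, "chr1", 210_000, 215_000)]
        g1 = GeneModel("g1", "chr1", "+", 212_000, 220_000)  # at DB's anchor
        g2 = GeneModel("g2", "chr1", "+", 11_000, 14_000)    # at DA's anchor
        res = assign_target_genes([d1, d2], loops, [g1, g2])
        assert res["targets"]["DA"] == ["g1"]  # duplicate loop deduplicated
        assert res["targets"]["DB"] == ["g2"]
        assert res["report"]["n_target_genes"] == 2

    def test_marked_overlap_report(self):
        dom, loops = self._setup()
        gene = GeneModel("g1", "chr1", "+", 201_000, 210_000)
        res = assign_target_genes([dom], loops, [gene],
                                  marked_gene_ids={"g1", "gX"})
        assert res["report"]["n_targets_also_marked"] == 1


class TestTermEnrichmentCorrelation:
    def _db(self):
        universe = {f"g{i}" for i in range(100)}
        term_db = {
            "t1": {f"g{i}" for i in range(10)},
            "t2": {f"g{i}" for i in range(10, 20)},
            "t3": {f"g{i}" for i in range(20, 30)},
            "t4": {f"g{i}" for i in range(30, 45)},
        }
        return universe, term_db

    def test_identical_sets_r_one(self):
        universe, term_db = self._db()
        # t1 and t2 fully hit, t3 hit 7/10 (p ~ 3.5e-3, EF ~ 2.6): three
        # terms pass the gates with non-constant -log10 p
        s = {f"g{i}" for i in range(27)}
        res = term_enrichment_correlation(s, s, term_db, universe)
        assert len(res["shared_terms"]) >= 3
        assert res["r"] == pytest.approx(1.0)

    def test_random_set_low_correlation(self, rng):
        universe, term_db = self._db()
        a = {f"g{i}" for i in range(12)} | {"g21", "g22", "g23", "g31", "g32"}
        rs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            b = set(r.choice(sorted(universe), size=15, replace=False).tolist())
            res = term_enrichment_correlation(a, b, term_db, universe)
            if res["r"] is not None:
                rs.append(res["r"])
        if rs:  # random sets rarely share enriched terms; near-zero on average
            assert abs(np.mean(rs)) < 0.7

    def test_too_few_shared_terms_skipped(self, caplog):
        universe, term_db = self._db()
        with caplog.at_level(logging.WARNING):
            res = term_enrichment_correlation(
                {"g50"}, {"g60"}, term_db, universe)
        assert res["r"] is None
        assert "skipped" in caplog.text

    def test_gene_outside_universe_rejected(self):
        universe, term_db = self._db()
        term_db["bad"] = {"not_a_gene"}
        with pytest.raises(ValueError, match="universe"):
            term_enrichment_correlation(set(), set(), term_db, universe)
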