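"""Hypergeometric enrichment, BH correction, and FFL enumeration."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fflrx.errors import DomainError
from fflrx.ffl_discovery import (FflCategory, benjamini_hochberg,
                                 enumerate_ffls, hypergeometric_overlap_p,
                                 score_pairs)
from fflrx.regnet import EdgeType, RegulatoryNetwork
from conftest import build_network


def enumeration_tail(total, n_mir, n_tf, k):
    """P(X >= k) by exhaustive enumeration of all C(total, n_tf) subsets."""
    marked = set(range(n_mir))
    hits = sum(1 for s in itertools.combinations(range(total), n_tf)
               if len(marked & set(s)) >= k)
    return hits / sum(1 for _ in itertools.combinations(range(total), n_tf))


class TestHypergeometricOverlap:
    def test_k_zero_is_certain(self):
        assert hypergeometric_overlap_p(4, 5, 0, 10) == 1.0

    def test_forced_overlap_is_certain(self):
        # every universe gene is a miRNA target -> overlap k = n_tf is forced
        assert hypergeometric_overlap_p(10, 3, 3, 10) == 1.0

    def test_worked_example_6_over_252(self):
        p = hypergeometric_overlap_p(4, 5, 4, 10)
        assert p == pytest.approx(6 / 252, rel=1e-12)

    def test_matches_enumeration_on_sampled_cases(self):
        cases = [(8, 3, 4, 2), (9, 5, 5, 3), (10, 4, 5, 4), (7, 6, 5, 4),
                 (12, 6, 6, 1), (11, 2, 9, 2)]
        for total, nm, nt, k in cases:
            expected = enumeration_tail(total, nm, nt, k)
            got = hypergeometric_overlap_p(nm, nt, k, total)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_non_increasing_in_k(self):
        ps = [hypergeometric_overlap_p(6, 7, k, 20) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            hypergeometric_overlap_p(4, 5, 5, 10)  # k > min
        with pytest.raises(DomainError):
            hypergeometric_overlap_p(11, 5, 2, 10)  # n_mir > total


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == [0.3]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_permutation_equivariant(self, ps):
        adj = benjamini_hochberg(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        perm = list(reversed(ps))
        assert benjamini_hochberg(perm) == pytest.approx(list(reversed(adj)))


def random_typed_network(rng, n_m=6, n_t=6, n_g=12, density=0.3):
    net = RegulatoryNetwork()
    mirnas = [f"m{i}" for i in range(n_m)]
    tfs = [f"t{i}" for i in range(n_t)]
    genes = [f"g{i}" for i in range(n_g)]
    for m in mirnas:
        for g in genes:
            if rng.random() < density:
                net.add_edge(m, g, EdgeType.MIR_GENE)
    for t in tfs:
        for g in genes:
            if rng.random() < density:
                net.add_edge(t, g, EdgeType.TF_GENE)
    for m in mirnas:
        for t in tfs:
            if rng.random() < density / 2:
                net.add_edge(m, t, EdgeType.MIR_TF)
            if rng.random() < density / 2:
                net.add_edge(t, m, EdgeType.TF_MIR)
    return net, mirnas, tfs, genes


def triad_oracle(net, mirnas, tfs):
    """O(|M||T||G|) brute-force FFL census by direct predicate checks."""
    mir_t = net.targets_by_source(EdgeType.MIR_GENE)
    tf_t = net.targets_by_source(EdgeType.TF_GENE)
    census = {c: set() for c in FflCategory}
    for m in mirnas:
        for t in tfs:
            common = mir_t.get(m, set()) & tf_t.get(t, set())
            if not common:
                continue
            m2t = net.has_edge(m, t, EdgeType.MIR_TF)
            t2m = net.has_edge(t, m, EdgeType.TF_MIR)
            if m2t and t2m:
                census[FflCategory.COMPOSITE_FFL].add((m, t))
            elif m2t:
                census[FflCategory.MIRNA_FFL].add((m, t))
            elif t2m:
                census[FflCategory.TF_FFL].add((m, t))
    return census


def forced_enrichment(net):
    """Every co-targeting pair, with p forced to 0 (no significance filter)."""
    return [replace(r, p_raw=0.0, p_adj=0.0) for r in score_pairs(net)]


class TestScorePairs:
    def test_single_pair_sharing_all_genes(self):
        edges = [("m1", f"g{i}", "MIR_GENE") for i in range(5)] + \
                [("t1", f"g{i}", "TF_GENE") for i in range(5)]
        net = build_network(edges)
        res = score_pairs(net)
        assert len(res) == 1
        r = res[0]
        assert (r.k, r.n_mir, r.n_tf, r.total) == (5, 5, 5, 5)
        assert r.p_adj == r.p_raw  # single test: BH is identity

    def test_zero_overlap_pairs_not_tested(self):
        net = build_network([("m1", "g1", "MIR_GENE"), ("m2", "g2", "MIR_GENE"),
                             ("t1", "g1", "TF_GENE"), ("t1", "g2", "TF_GENE")])
        tested = {(r.mirna_id, r.tf_id) for r in score_pairs(net)}
        assert tested == {("m1", "t1"), ("m2", "t1")}
        # in union mode g3 exists only for the miRNA: still no (m3, t1) test
        net.add_edge("m3", "g3", EdgeType.MIR_GENE)
        tested = {(r.mirna_id, r.tf_id) for r in score_pairs(net, "union")}
        assert ("m3", "t1") not in tested

    def test_raw_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        net, *_ = random_typed_network(rng, n_m=4, n_t=4, n_g=10, density=0.35)
        for r in score_pairs(net):
            expected = enumeration_tail(r.total, r.n_mir, r.n_tf, r.k)
            assert r.p_raw == pytest.approx(expected, rel=1e-12)

    def test_universe_modes(self):
        net = build_network([("m1", "g1", "MIR_GENE"), ("m1", "g2", "MIR_GENE"),
                             ("t1", "g1", "TF_GENE"), ("t1", "g3", "TF_GENE")])
        assert score_pairs(net, "intersection")[0].total == 1
        assert score_pairs(net, "union")[0].total == 3

    def test_empty_universe_raises(self):
        net = build_network([("m1", "g1", "MIR_GENE"), ("t1", "g2", "TF_GENE")])
        with pytest.raises(DomainError):
            score_pairs(net, "intersection")


class TestEnumerateFfls:
    def test_planted_composite(self, planted_composite_net):
        ffls = enumerate_ffls(planted_composite_net,
                              forced_enrichment(planted_composite_net), 1.0)
        assert len(ffls) == 1
        f = ffls[0]
        assert f.category is FflCategory.COMPOSITE_FFL
        assert f.common_genes == {"g1", "g2"}

    def test_planted_mirna_ffl_without_reciprocal(self):
        net = build_network([("m1", "t1", "MIR_TF"), ("m1", "g1", "MIR_GENE"),
                             ("t1", "g1", "TF_GENE")])
        ffls = enumerate_ffls(net, forced_enrichment(net), 1.0)
        assert [f.category for f in ffls] == [FflCategory.MIRNA_FFL]

    def test_alpha_strict_comparison(self, planted_composite_net):
        res = score_pairs(planted_composite_net)
        at_p = res[0].p_adj
        assert enumerate_ffls(planted_composite_net, res, at_p) == []
        assert len(enumerate_ffls(planted_composite_net, res,
                                  at_p * 1.0000001)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triad_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net, mirnas, tfs, _ = random_typed_network(rng)
        ffls = enumerate_ffls(net, forced_enrichment(net), 1.0)
        got = {c: set() for c in FflCategory}
        for f in ffls:
            got[f.category].add((f.mirna_id, f.tf_id))
        assert got == triad_oracle(net, mirnas, tfs)

    def test_categories_mutually_exclusive_per_pair(self):
        rng = np.random.default_rng(42)
        net, *_ = random_typed_network(rng, density=0.5)
        ffls = enumerate_ffls(net, forced_enrichment(net), 1.0)
        pairs = [(f.mirna_id, f.tf_id) for f in ffls]
        assert len(pairs) == len(set(pairs))

    def test_common_genes_subset_of_both_target_sets(self):
        rng = np.random.default_rng(8)
        net, *_ = random_typed_network(rng)
        mir_t = net.targets_by_source(EdgeType.MIR_GENE)
        tf_t = net.targets_by_source(EdgeType.TF_GENE)
        for f in enumerate_ffls(net, forced_enrichment(net), 1.0):
            assert f.common_genes <= mir_t[f.mirna_id]
            assert f.common_genes <= tf_t[f.tf_id]
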