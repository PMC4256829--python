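"""Generator determinism, ground-truth consistency, and planted recovery."""

import hashlib
import json
from dataclasses import replace

import numpy as np
import pytest

from fflrx.edge_inference import (assign_peaks_to_targets, consensus_vote,
                                  find_seed_sites)
from fflrx.errors import ConfigurationError
from fflrx.ffl_discovery import FflCategory, enumerate_ffls, score_pairs
from fflrx.regnet import EdgeType, ExpressionList
from fflrx.synthetic_data import (GroundTruth, SynthesisConfig,
                                  generate_bundle, generate_network,
                                  generate_peaks, generate_prediction_matrix,
                                  generate_sequences,
                                  generate_validation_and_drug_tables,
                                  simulate_prediction_matrix)
from fflrx.validation import filter_ppi
from fflrx.repurposing import (DrugMirnaEffect, DrugRecord,
                               nominate_candidates)


def small_config(**kw):
    defaults = dict(seed=5, n_mirnas=8, n_tfs=8, n_genes=30,
                    n_planted_composite=3, n_planted_mirna_ffl=1,
                    n_planted_tf_ffl=1, genes_per_planted_ffl=4,
                    background_edge_density=0.0, n_drugs=20, n_true_drugs=4)
    defaults.update(kw)
    return SynthesisConfig(**defaults)


def dir_hashes(path):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.iterdir())}


class TestNetworkGeneration:
    def test_noise_free_planting_recovered_exactly(self):
        cfg = small_config(n_planted_composite=3, n_planted_mirna_ffl=0,
                           n_planted_tf_ffl=0, genes_per_planted_ffl=5)
        net, truth = generate_network(cfg)
        res = score_pairs(net)
        ffls = enumerate_ffls(net, res, 1.0)
        comps = [f for f in ffls if f.category is FflCategory.COMPOSITE_FFL]
        assert len(comps) == 3
        planted = {(f.mirna, f.tf): set(f.genes)
                   for f in truth.planted_ffls}
        for f in comps:
            assert f.common_genes == planted[(f.mirna_id, f.tf_id)]

    def test_planted_categories_exact_under_background(self):
        cfg = small_config(background_edge_density=0.08)
        net, truth = generate_network(cfg)
        by_cat = {c.value: set() for c in FflCategory}
        for f in truth.planted_ffls:
            by_cat[f.category].add((f.mirna, f.tf))
        ffls = enumerate_ffls(net, [replace(r, p_raw=0.0, p_adj=0.0)
                                    for r in score_pairs(net)], 1.0)
        found = {(f.mirna_id, f.tf_id): f.category.value for f in ffls}
        for cat, pairs in by_cat.items():
            for pair in pairs:
                assert found[pair] == cat  # background never recategorizes

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthesisConfig(n_mirnas=4, n_tfs=4, n_planted_composite=5,
                            n_planted_mirna_ffl=0, n_planted_tf_ffl=0)


class TestPredictionMatrix:
    def test_perfect_sensitivity_recovers_truth(self):
        cfg = small_config(algo_sensitivity=1.0, algo_fpr=0.0)
        _, truth = generate_network(cfg)
        matrix = generate_prediction_matrix(cfg, truth)
        true_pairs = {tuple(p) for p in truth.true_mir_gene_pairs}
        assert consensus_vote(matrix, matrix.n_algorithms) == true_pairs

    def test_zero_sensitivity_empty(self):
        cfg = small_config(algo_sensitivity=0.0, algo_fpr=0.0)
        _, truth = generate_network(cfg)
        matrix = generate_prediction_matrix(cfg, truth)
        assert consensus_vote(matrix, 1) == set()

    def test_consensus_fraction_near_binomial_tail(self):
        rng = np.random.default_rng(13)
        true_pairs = [(f"m{i}", f"g{i}") for i in range(200)]
        false_pairs = [(f"m{i}", f"h{j}") for i in range(40) for j in range(50)]
        matrix = simulate_prediction_matrix(
            rng, [f"a{i}" for i in range(10)], true_pairs, false_pairs,
            sensitivity=0.9, fpr=0.05)
        kept = consensus_vote(matrix, 8)
        frac = len(kept & set(true_pairs)) / len(true_pairs)
        tail = 0.9298  # P(X >= 8), X ~ Binomial(10, 0.9)
        sigma = (tail * (1 - tail) / len(true_pairs)) ** 0.5
        assert abs(frac - tail) <= 3 * sigma


class TestSequences:
    def test_planted_sites_recovered_exactly(self):
        cfg = small_config()
        _, truth = generate_network(cfg)
        mirnas, utrs, sites = generate_sequences(cfg, truth)
        expected = {(s["mirna"], s["gene"], s["site_type"], s["start"])
                    for s in sites}
        found = set()
        for m in mirnas:
            for u in utrs:
                for s in find_seed_sites(m, u):
                    found.add((s.mirna_id, s.gene_id, s.site_type, s.start))
        assert found == expected

    def test_site_free_utrs_have_no_sites(self):
        cfg = small_config(n_planted_composite=0, n_planted_mirna_ffl=0,
                           n_planted_tf_ffl=0)
        net, truth = generate_network(cfg)
        assert not truth.true_mir_gene_pairs
        mirnas, utrs, sites = generate_sequences(cfg, truth)
        assert sites == []
        assert all(not find_seed_sites(m, u) for m in mirnas for u in utrs)

    def test_site_substring_matches_pattern(self):
        cfg = small_config()
        _, truth = generate_network(cfg)
        mirnas, utrs, sites = generate_sequences(cfg, truth)
        by_id = {m.id: m for m in mirnas}
        utr_of = {u.gene_id: u for u in utrs}
        for s in sites:
            pattern = by_id[s["mirna"]].site_patterns()[s["site_type"]]
            seq = utr_of[s["gene"]].sequence
            assert seq[s["start"]:s["start"] + len(pattern)] == pattern


class TestPeaks:
    def test_peak_assignment_recovers_tf_edges_exactly(self):
        cfg = small_config(background_edge_density=0.05)
        net, _ = generate_network(cfg)
        peaks, annotations = generate_peaks(cfg, net)
        edges = assign_peaks_to_targets(peaks, annotations,
                                        cfg.promoter_upstream,
                                        cfg.promoter_downstream)
        got = {(e.source, e.target, e.edge_type) for e in edges}
        want = {(e.source, e.target, e.edge_type) for e in net.edges
                if e.edge_type in (EdgeType.TF_GENE, EdgeType.TF_MIR)}
        assert got == want


class TestValidationAndDrugTables:
    def test_signal_ppi_survive_filter_exactly(self):
        cfg = small_config()
        _, truth = generate_network(cfg)
        tables = generate_validation_and_drug_tables(cfg, truth)
        kept = {(r.gene_a, r.gene_b) for r in filter_ppi(tables["ppi"], 0.4)}
        assert kept == {tuple(p) for p in truth.signal_ppi_pairs}

    def test_deg_coverage_nine_of_fifteen(self):
        cfg = SynthesisConfig(seed=2, n_mirnas=20, n_tfs=20, n_genes=100,
                              n_planted_composite=15, n_planted_mirna_ffl=0,
                              n_planted_tf_ffl=0, genes_per_planted_ffl=3,
                              background_edge_density=0.0, deg_coverage=0.6)
        net, truth = generate_network(cfg)
        generate_validation_and_drug_tables(cfg, truth)
        assert len(truth.deg_mirnas) == 9
        ffls = enumerate_ffls(net, [replace(r, p_raw=0.0, p_adj=0.0)
                                    for r in score_pairs(net)], 1.0)
        from fflrx.validation import confirm_ffls_with_expression

        report = confirm_ffls_with_expression(
            ffls, ExpressionList("miRNA", dict(truth.deg_mirnas)))
        assert report.n_confirmed == 9

    def test_true_drugs_nominated_decoys_never(self):
        cfg = small_config(background_edge_density=0.02)
        net, truth = generate_network(cfg)
        tables = generate_validation_and_drug_tables(cfg, truth)
        registry = {
            r["drug_id"]: DrugRecord(
                r["drug_id"], r["name"], r["approved"], r["boxed_warning"],
                frozenset(r["atc_level1"].split(",")))
            for r in tables["drugs"]
        }
        effects = [DrugMirnaEffect(e["drug_id"], e["mirna_id"],
                                   e["direction"], e["source"])
                   for e in tables["effects"]]
        ffls = enumerate_ffls(net, [replace(r, p_raw=0.0, p_adj=0.0)
                                    for r in score_pairs(net)], 1.0)
        cands = {c.drug_id for c in nominate_candidates(ffls, effects, registry)}
        assert set(truth.true_drugs) <= cands
        assert not cands & set(truth.decoy_drugs)

    def test_decoy_only_registry_yields_no_candidates(self):
        cfg = small_config(n_true_drugs=0)
        net, truth = generate_network(cfg)
        tables = generate_validation_and_drug_tables(cfg, truth)
        registry = {
            r["drug_id"]: DrugRecord(
                r["drug_id"], r["name"], r["approved"], r["boxed_warning"],
                frozenset(r["atc_level1"].split(",")))
            for r in tables["drugs"]
        }
        effects = [DrugMirnaEffect(e["drug_id"], e["mirna_id"],
                                   e["direction"], e["source"])
                   for e in tables["effects"]]
        ffls = enumerate_ffls(net, [replace(r, p_raw=0.0, p_adj=0.0)
                                    for r in score_pairs(net)], 1.0)
        assert nominate_candidates(ffls, effects, registry) == []


class TestBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(background_edge_density=0.03)
        generate_bundle(cfg, tmp_path / "a")
        generate_bundle(cfg, tmp_path / "b")
        assert dir_hashes(tmp_path / "a") == dir_hashes(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        generate_bundle(small_config(seed=1), tmp_path / "a")
        generate_bundle(small_config(seed=2), tmp_path / "b")
        assert dir_hashes(tmp_path / "a") != dir_hashes(tmp_path / "b")

    def test_ground_truth_json_round_trip_and_consistency(self, tmp_path):
        cfg = small_config(background_edge_density=0.03)
        truth = generate_bundle(cfg, tmp_path / "a")
        loaded = GroundTruth.from_json(tmp_path / "a" / "ground_truth.json")
        assert loaded == truth
        # every planted edge appears in the emitted TSVs
        mir_gene = (tmp_path / "a" / "mir_gene.tsv").read_text()
        for f in truth.planted_ffls:
            for g in f.genes:
                assert f"{f.mirna}\t{g}" in mir_gene
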