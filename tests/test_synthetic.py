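"""Synthetic-data generator: planted truth, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from brainmr.simulate import (
    GenotypePanel,
    empirical_ld,
    measure_metadata,
    simulate_annotations,
    simulate_exposure_gwas,
    simulate_expression,
    simulate_network,
    simulate_outcome_panel,
    simulate_reference_panel,
)


class TestReferencePanel:
    def test_block_correlation_near_target(self, ld_block_panel):
        r = np.corrcoef(ld_block_panel.dosages, rowvar=False)
        off = np.abs(r[~np.eye(10, dtype=bool)])
        assert np.all(np.abs(off - 0.8) < 0.1)

    def test_independent_blocks_nearly_uncorrelated(self):
        panel = simulate_reference_panel(500, 5, [(1, 0.0)] * 5, seed=2)
        r = np.corrcoef(panel.dosages, rowvar=False)
        assert np.abs(r[~np.eye(5, dtype=bool)]).max() < 0.15

    def test_same_seed_is_bit_identical(self):
        a = simulate_reference_panel(100, 6, [(3, 0.5), (3, 0.2)], seed=7)
        b = simulate_reference_panel(100, 6, [(3, 0.5), (3, 0.2)], seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_panel_invariants(self, ld_block_panel):
        d = ld_block_panel.dosages
        assert d.min() >= 0 and d.max() <= 2
        af = d.mean(axis=0) / 2
        assert np.all((af > 0) & (af < 1))
        assert not ld_block_panel.variants["variant_id"].duplicated().any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_individuals=10, n_variants=2, block_structure=[(2, 0.5)]),
            dict(n_individuals=100, n_variants=2, block_structure=[(2, 0.96)]),
            dict(n_individuals=100, n_variants=3, block_structure=[(2, 0.5)]),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_reference_panel(seed=1, **kwargs)


class TestExposureGwas:
    def test_recovers_planted_effect(self):
        panel = simulate_reference_panel(2000, 5, [(1, 0.0)] * 5, (0.3, 0.5), seed=3)
        stats = simulate_exposure_gwas(panel, {"var0000": 0.5}, noise_sd=1.0, seed=3)
        row = stats.table.set_index("variant_id").loc["var0000"]
        assert abs(row["beta"] - 0.5) < 3 * row["se"]

    def test_null_type_i_calibration(self):
        panel = simulate_reference_panel(300, 5, [(1, 0.0)] * 5, seed=4)
        hits = []
        for rep in range(200):
            stats = simulate_exposure_gwas(panel, {}, noise_sd=1.0, seed=rep)
            hits.append(stats.table["p"] < 0.05)
        frac = np.concatenate(hits).mean()
        assert 0.02 < frac < 0.09  # ~3 binomial SDs around 0.05

    def test_degenerate_inputs_rejected(self, ld_block_panel):
        with pytest.raises(ValueError):
            simulate_exposure_gwas(ld_block_panel, {}, noise_sd=0.0, seed=1)
        tiny = GenotypePanel(
            ["i0"],
            pd.DataFrame(
                {"variant_id": ["v"], "chrom": "1", "pos": [1],
                 "effect_allele": "A", "other_allele": "G", "maf": [0.5]}
            ),
            np.array([[1]]),
        )
        with pytest.raises(ValueError):
            simulate_exposure_gwas(tiny, {}, noise_sd=1.0, seed=1)
        with pytest.raises(KeyError):
            simulate_exposure_gwas(ld_block_panel, {"nope": 0.1}, seed=1)


class TestOutcomePanel:
    def test_causal_bookkeeping_and_metadata(self):
        panel = simulate_reference_panel(200, 4, [(4, 0.3)], seed=7)
        meta = measure_metadata(120, [f"r{i}" for i in range(10)])
        planted = meta["measure_id"].iloc[:6].tolist()
        stats, matrix, meta2 = simulate_outcome_panel(
            panel, {"var0000": 0.3}, {m: 0.3 for m in planted}, 120,
            region_labels=[f"r{i}" for i in range(10)], seed=7,
        )
        assert set(stats) == set(meta2["measure_id"])
        assert matrix.shape == (200, 120)
        pd.testing.assert_frame_equal(meta, meta2)
        assert set(meta2["hemisphere"]) == {"left", "right"}
        assert set(meta2["modality"]) == {"GMV", "CT"}

    def test_unknown_measure_rejected(self):
        panel = simulate_reference_panel(100, 2, [(2, 0.2)], seed=1)
        with pytest.raises(KeyError):
            simulate_outcome_panel(panel, {}, {"not_a_measure": 0.2}, 10, seed=1)

    def test_identical_measure_blocks_give_exact_neff(self):
        from brainmr.multiplicity import effective_tests_pca

        panel = simulate_reference_panel(300, 2, [(2, 0.2)], seed=5)
        _, matrix, _ = simulate_outcome_panel(
            panel, {}, {}, 100, measure_blocks=[(10, 1.0)] * 10, seed=5,
        )
        assert effective_tests_pca(matrix) == 10


class TestExpression:
    def test_probe_bookkeeping(self):
        expr = simulate_expression(["A", "B"], 3, 50, probes_per_gene=3,
                                   target_region="A", seed=1)
        assert expr.values.shape == (150, 6)
        assert expr.probe_to_gene.nunique() == 50

    def test_planted_shift_visible_in_target_region(self):
        expr = simulate_expression(
            ["MTG", "rest"], 20, 50, 1, {"g0000": 3.0}, "MTG", noise_sd=0.5, seed=2
        )
        in_t = expr.sample_to_region == "MTG"
        row = expr.values.iloc[0]
        diff = row[in_t.values].mean() - row[~in_t.values].mean()
        assert 2.5 < diff < 3.5

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            simulate_expression(["A", "B"], 3, 10, 1, {"zzz": 2.0}, "A", seed=1)


class TestAnnotations:
    def test_planted_term_draws_from_designated_set(self):
        genes = [f"g{i:04d}" for i in range(1000)]
        planted = genes[:20]
        table = simulate_annotations(
            genes, 10, (10, 10), {"ont:t0000": 0.8}, planted, seed=1, ontology="ont"
        )
        term = {t.term_id: t for t in table.terms}["ont:t0000"]
        assert len(set(term.genes) & set(planted)) >= 4  # >= half of 0.8 * 10

    def test_members_subset_of_universe(self):
        genes = [f"g{i}" for i in range(50)]
        table = simulate_annotations(genes, 5, (3, 10), seed=3)
        for t in table.terms:
            assert set(t.genes) <= set(genes)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotations([], 5, (3, 10), seed=1)
        with pytest.raises(ValueError):
            simulate_annotations(["a", "b"], 5, (3, 10), seed=1)  # term > universe


class TestNetwork:
    def test_module_edge_count_matches_binomial_expectation(self):
        genes = [f"g{i}" for i in range(200)]
        module = genes[:20]
        g = simulate_network(genes, 0.01, module, 0.3, seed=1)
        internal = g.subgraph(module).number_of_edges()
        n_pairs = 20 * 19 // 2  # 190; expect 57 +- ~6.3 (binomial SD)
        assert abs(internal - 0.3 * n_pairs) < 4 * np.sqrt(n_pairs * 0.3 * 0.7)

    def test_equal_densities_rejected(self):
        with pytest.raises(ValueError):
            simulate_network(["a", "b", "c"], 0.1, ["a", "b"], 0.1, seed=1)

    def test_same_seed_same_edges(self):
        genes = [f"g{i}" for i in range(50)]
        a = simulate_network(genes, 0.05, seed=9)
        b = simulate_network(genes, 0.05, seed=9)
        assert set(a.edges) == set(b.edges)


def test_empirical_ld_is_valid_correlation_matrix(ld_block_panel):
    ld = empirical_ld(ld_block_panel)
    assert np.allclose(np.diag(ld.r), 1.0)
    assert np.allclose(ld.r, ld.r.T)
    assert np.linalg.eigvalsh(ld.r).min() > -1e-8
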