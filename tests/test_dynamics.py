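import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, mannwhitneyu
from sklearn.metrics import adjusted_rand_score

import kerahet as kh
from kerahet.dynamics import natural_cubic_basis
from kerahet.synthetic import ExpressionSimSpec

from conftest import make_expr


class TestNaturalCubicBasis:
    def test_shape_and_linear_tails(self):
        t = np.linspace(0, 1, 200)
        basis, knots = natural_cubic_basis(t, df=3)
        assert basis.shape == (200, 3)
        # natural constraint: extrapolation beyond the boundary knots is linear
        far = np.array([2.0, 3.0, 4.0])
        ext, _ = natural_cubic_basis(far, df=3, knots=knots)
        d1 = np.diff(ext, axis=0)
        np.testing.assert_allclose(d1[0], d1[1], rtol=1e-9)


class TestDetectDynamicGenes:
    def test_planted_recovery(self):
        spec = ExpressionSimSpec(
            n_genes=2000, n_cells_control=100, n_cells_treated=100,
            n_marker_genes_per_state=0, n_dispersed_genes=0,
            n_dynamic_genes=200, dynamic_amplitude=2.0, seed=7,
        )
        expr, ann, truth = kh.simulate_expression(spec)
        table = kh.detect_dynamic_genes(expr, ann)
        merged = table.merge(
            truth.genes[["gene", "dynamic"]], on="gene", suffixes=("_called", "_true")
        )
        recall = (
            merged["dynamic_called"] & merged["dynamic_true"]
        ).sum() / merged["dynamic_true"].sum()
        assert recall >= 0.8

    def test_null_false_positive_rate(self, null_sim):
        _, expr, ann, _ = null_sim
        table = kh.detect_dynamic_genes(expr, ann)
        assert (table["fdr_q"] < 0.05).mean() <= 0.05

    def test_constant_gene_not_flagged(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([np.full(40, 6.0), rng.uniform(0, 60, (5, 40))])
        expr = make_expr(vals, genes=["flat"] + [f"g{i}" for i in range(5)])
        ann = pd.DataFrame({"cell_id": expr.cells,
                            "pseudotime": np.linspace(0, 1, 40)})
        table = kh.detect_dynamic_genes(expr, ann)
        row = table[table["gene"] == "flat"].iloc[0]
        assert row["p"] == 1.0 and not row["dynamic"]

    def test_statistic_nonnegative_p_monotone(self, default_sim):
        _, expr, ann, _ = default_sim
        table = kh.detect_dynamic_genes(expr, ann)
        assert (table["lrt_statistic"] >= 0).all()
        ordered = table.sort_values("lrt_statistic")
        assert (np.diff(ordered["p"].to_numpy()) <= 1e-12).all()

    def test_too_few_cells_errors(self):
        expr = make_expr(np.ones((3, 10)))
        ann = pd.DataFrame({"cell_id": expr.cells,
                            "pseudotime": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError, match="20"):
            kh.detect_dynamic_genes(expr, ann)


class TestClusterTemporalPatterns:
    def test_four_planted_patterns_recovered(self):
        spec = ExpressionSimSpec(
            n_genes=1500, n_cells_control=100, n_cells_treated=100,
            n_marker_genes_per_state=0, n_dispersed_genes=0,
            n_dynamic_genes=200, dynamic_amplitude=2.5, seed=2,
        )
        expr, ann, truth = kh.simulate_expression(spec)
        tg = truth.genes
        dyn = list(tg.loc[tg["dynamic"], "gene"])
        clusters, _ = kh.cluster_temporal_patterns(expr, ann, dyn, k=4)
        merged = clusters.merge(tg[["gene", "temporal_pattern"]], on="gene")
        ari = adjusted_rand_score(merged["temporal_pattern"], merged["temporal_cluster"])
        assert ari >= 0.8

    def test_peak_ordering_contract(self):
        # gene peaking at grid start must get peak 0 and sort first
        n = 60
        t = np.linspace(0, 1, n)
        rng = np.random.default_rng(1)
        first = 40.0 * (1.0 - t)  # peak at 0
        others = [40.0 * np.exp(-0.5 * ((t - c) / 0.1) ** 2) + rng.uniform(0, 0.5, n)
                  for c in (0.3, 0.6, 0.9)]
        expr = make_expr(np.vstack([first, *others]),
                         genes=["early", "g1", "g2", "g3"])
        ann = pd.DataFrame({"cell_id": expr.cells, "pseudotime": t})
        clusters, _ = kh.cluster_temporal_patterns(
            expr, ann, ["early", "g1", "g2", "g3"], k=2
        )
        assert clusters["gene"].iloc[0] == "early"
        assert clusters["peak_pseudotime"].iloc[0] == 0.0

    def test_duplicated_gene_same_cluster(self):
        n = 50
        t = np.linspace(0, 1, n)
        rng = np.random.default_rng(2)
        curve = 30.0 * t
        noise = [rng.uniform(0, 30, n) for _ in range(4)]
        expr = make_expr(np.vstack([curve, curve, *noise]),
                         genes=["dup1", "dup2", "n1", "n2", "n3", "n4"])
        ann = pd.DataFrame({"cell_id": expr.cells, "pseudotime": t})
        clusters, _ = kh.cluster_temporal_patterns(expr, ann, list(expr.genes), k=3)
        pair = clusters.set_index("gene").loc[["dup1", "dup2"], "temporal_cluster"]
        assert pair.iloc[0] == pair.iloc[1]

    def test_more_clusters_than_genes_errors(self):
        expr = make_expr(np.random.default_rng(0).uniform(0, 10, (3, 30)))
        ann = pd.DataFrame({"cell_id": expr.cells,
                            "pseudotime": np.linspace(0, 1, 30)})
        with pytest.raises(ValueError):
            kh.cluster_temporal_patterns(expr, ann, list(expr.genes), k=4)


class TestProliferationIndex:
    def test_all_markers_constant_errors(self):
        expr = make_expr(np.full((2, 10), 4.0), genes=["m1", "m2"])
        with pytest.raises(ValueError, match="constant"):
            kh.proliferation_index(expr, ["m1", "m2"])

    def test_maximal_cell_scores_one(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 20, size=(3, 15))
        vals[:, 0] = 100.0  # cell 0 has the max of every marker
        expr = make_expr(vals)
        idx = kh.proliferation_index(expr, list(expr.genes))
        assert idx.iloc[0] == pytest.approx(1.0)
        assert idx.between(0, 1).all()

    def test_no_marker_present_errors(self):
        expr = make_expr(np.ones((2, 5)))
        with pytest.raises(ValueError, match="missing"):
            kh.proliferation_index(expr, ["absent1"])

    def test_proliferative_states_score_higher(self, default_sim):
        # S-phase stand-ins: planted markers of the proliferative states C and D
        _, expr, ann, truth = default_sim
        tg = truth.genes
        markers = list(tg.loc[tg["marker_state"].isin(["C", "D"]), "gene"])[:20]
        idx = kh.proliferation_index(expr, markers)
        state = ann.set_index("cell_id")["state"]
        high = idx[state.isin(["C", "D"]).to_numpy()]
        low = idx[state.isin(["A", "B"]).to_numpy()]
        assert mannwhitneyu(high, low, alternative="greater").pvalue < 0.01


class TestTFOverrepresentation:
    def test_disjoint_targets_p_one(self, default_sim):
        _, expr, ann, _ = default_sim
        universe = list(expr.genes[:1000])
        dynamic = universe[:100]
        targets = kh.GeneSetCollection({expr.genes[0]: universe[500:550]})
        res = kh.tf_overrepresentation(dynamic, universe, targets, expr, ann)
        assert res["p"].iloc[0] == pytest.approx(
            float(hypergeom.sf(-1, 1000, 50, 100))
        )

    def test_hypergeometric_enumeration_oracle(self, default_sim):
        _, expr, ann, _ = default_sim
        universe = list(expr.genes[:1000])
        dynamic = universe[:100]
        # 50 targets of which 25 dynamic
        targets = kh.GeneSetCollection({expr.genes[0]: universe[75:125]})
        res = kh.tf_overrepresentation(dynamic, universe, targets, expr, ann)
        enum = sum(
            hypergeom.pmf(k, 1000, 50, 100) for k in range(25, 51)
        )
        assert res["p"].iloc[0] == pytest.approx(enum, abs=1e-10)

    def test_planted_regulators_flagged(self, default_sim):
        _, expr, ann, truth = default_sim
        genes = kh.select_analysis_genes(expr)
        dyn_table = kh.detect_dynamic_genes(expr, ann, analysis_genes=genes)
        dynamic = list(dyn_table.loc[dyn_table["dynamic"], "gene"])
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            coll, tf_truth = kh.simulate_tf_targets(truth.genes, seed=seed)
            res = kh.tf_overrepresentation(dynamic, genes, coll, expr, ann)
            merged = res.merge(tf_truth, on="tf")
            planted_q = merged.loc[merged["planted"], "q"]
            hits += (planted_q < 0.05).all()
        assert hits / n_runs >= 0.9

    def test_direction_grouping(self, default_sim):
        _, expr, ann, truth = default_sim
        tg = truth.genes
        up_in_d = tg.loc[tg["marker_state"] == "D", "gene"].iloc[0]
        up_in_a = tg.loc[tg["marker_state"] == "A", "gene"].iloc[0]
        universe = list(expr.genes)
        coll = kh.GeneSetCollection({up_in_d: universe[:30], up_in_a: universe[:30]})
        res = kh.tf_overrepresentation(universe[:10], universe, coll, expr, ann)
        res = res.set_index("tf")
        assert res.loc[up_in_d, "direction"] == "positive"
        assert res.loc[up_in_a, "direction"] == "negative"

    def test_unexpressed_tf_filtered_before_correction(self, default_sim):
        _, expr, ann, _ = default_sim
        universe = list(expr.genes)
        coll = kh.GeneSetCollection({"not_a_gene": universe[:30]})
        res = kh.tf_overrepresentation(universe[:10], universe, coll, expr, ann)
        assert not res["expressed"].iloc[0]
        assert np.isnan(res["q"].iloc[0])
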