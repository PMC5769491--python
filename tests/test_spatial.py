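import numpy as np
import pandas as pd
import pytest

import kerahet as kh
from kerahet.synthetic import SpatialSimSpec


def table_from_xy(xy, **cols):
    n = len(xy)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "is_transgene": cols.pop("is_transgene", np.zeros(n, dtype=bool)),
        "condition": cols.pop("condition", "control"),
        "replicate": cols.pop("replicate", "r1"),
    }
    base.update(cols)
    return pd.DataFrame(base)


def spatial_summaries(table, radius=20.0):
    frames = []
    for _, sub in table.groupby(["condition", "replicate"], sort=True):
        sub = sub.reset_index(drop=True)
        graph = kh.build_neighbour_graph(sub, radius)
        frames.append(kh.neighbour_summaries(sub, graph))
    return pd.concat(frames, ignore_index=True)


class TestNeighbourGraph:
    def test_two_distant_cells_no_edge(self):
        tab = table_from_xy(np.array([[0.0, 0.0], [25.0, 0.0]]))
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        assert graph.nnz == 0

    def test_hexagonal_interior_six_neighbours(self):
        spec = SpatialSimSpec(layout="hexagonal", lattice_spacing=15.0,
                              field_size=(300, 300), n_replicates=1,
                              conditions=("control",), seed=0)
        tab, _ = kh.simulate_spatial(spec)
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        deg = np.asarray(graph.sum(axis=1)).ravel()
        xy = tab[["x_um", "y_um"]].to_numpy()
        interior = ((xy > 30) & (xy < 270)).all(axis=1)
        assert (deg[interior] == 6).all()

    def test_poisson_mean_degree_matches_closed_form(self):
        side = 1000.0
        spec = SpatialSimSpec(layout="poisson", n_cells=20000,
                              field_size=(side, side), n_replicates=1,
                              conditions=("control",), seed=1)
        tab, _ = kh.simulate_spatial(spec)
        graph = kh.build_neighbour_graph(tab, radius=20.0, wrap=(side, side))
        lam = len(tab) / side**2
        expected = lam * np.pi * 20.0**2
        assert kh.mean_neighbour_count(graph) == pytest.approx(expected, rel=0.02)

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 200, size=(300, 2))
        graph = kh.build_neighbour_graph(table_from_xy(xy), radius=20.0)
        assert (graph != graph.T).nnz == 0
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = kh.build_neighbour_graph(table_from_xy(xy @ R.T + 57.0), radius=20.0)
        assert (graph != moved).nnz == 0

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 100, size=(200, 2))
        small = kh.build_neighbour_graph(table_from_xy(xy), radius=10.0)
        large = kh.build_neighbour_graph(table_from_xy(xy), radius=25.0)
        deg_small = np.asarray(small.sum(axis=1)).ravel()
        deg_large = np.asarray(large.sum(axis=1)).ravel()
        assert (deg_large >= deg_small).all()

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            kh.build_neighbour_graph(table_from_xy(np.zeros((2, 2))), radius=0.0)


class TestNeighbourSummaries:
    def star(self, intensities, neighbour_tg):
        # index transgene cell at origin with neighbours on a 10 um ring
        n = len(intensities)
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
        xy = np.vstack([[0.0, 0.0], 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])])
        tg = np.array([True, *neighbour_tg])
        return table_from_xy(xy, is_transgene=tg, opp=np.r_[50.0, intensities])

    def test_mean_intensity_arithmetic(self):
        tab = self.star([10.0, 20.0, 30.0], [False] * 3)
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        summ = kh.neighbour_summaries(tab, graph)
        assert summ["mean_neighbour_opp"].iloc[0] == pytest.approx(20.0)
        assert summ["n_neighbours"].iloc[0] == 3
        assert not summ["excluded"].iloc[0]

    def test_exclusion_rule(self):
        tab = self.star([1.0, 2.0, 3.0, 4.0], [True, True, True, False])
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        summ = kh.neighbour_summaries(tab, graph)
        row = summ[summ["index_cell_id"] == "c0"].iloc[0]
        assert row["n_transgene_neighbours"] == 3
        assert row["excluded"]

    def test_exclusion_matches_brute_force(self):
        spec = SpatialSimSpec(n_cells=1500, n_replicates=1,
                              conditions=("treated",), seed=5)
        tab, _ = kh.simulate_spatial(spec)
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        summ = kh.neighbour_summaries(tab, graph).set_index("index_cell_id")
        xy = tab[["x_um", "y_um"]].to_numpy()
        tg = tab["is_transgene"].to_numpy()
        for i in np.flatnonzero(tg):
            d = np.linalg.norm(xy - xy[i], axis=1)
            n_tg = int((tg & (d <= 20.0) & (d > 0)).sum())
            row = summ.loc[tab["cell_id"].iloc[i]]
            assert row["n_transgene_neighbours"] == n_tg
            assert row["excluded"] == (n_tg > 2)

    def test_isolated_index_cell_not_excluded(self):
        xy = np.array([[0.0, 0.0], [100.0, 100.0]])
        tab = table_from_xy(xy, is_transgene=np.array([True, False]), opp=[1.0, 2.0])
        graph = kh.build_neighbour_graph(tab, radius=20.0)
        summ = kh.neighbour_summaries(tab, graph)
        row = summ.iloc[0]
        assert row["n_neighbours"] == 0 and not row["excluded"]
        assert np.isnan(row["mean_neighbour_opp"])


class TestCompareConditions:
    def test_planted_contact_effect_detected(self):
        spec = SpatialSimSpec(n_cells=1000, contact_effect=50.0, seed=6)
        tab, _ = kh.simulate_spatial(spec)
        summ = spatial_summaries(tab)
        comp = kh.compare_conditions(tab, summ, "opp")
        p = comp.loc[comp["measure"] == "neighbour_mean", "p"].iloc[0]
        assert p < 0.01

    def test_low_calcium_null_uniform(self):
        hits = 0
        for seed in range(20):
            spec = SpatialSimSpec(n_cells=700, contact_effect=50.0,
                                  low_calcium=True, seed=seed)
            tab, _ = kh.simulate_spatial(spec)
            summ = spatial_summaries(tab)
            comp = kh.compare_conditions(tab, summ, "opp")
            p = comp.loc[comp["measure"] == "neighbour_mean", "p"].iloc[0]
            hits += p < 0.05
        assert hits / 20 <= 0.1

    def test_permuted_labels_control_significance(self):
        # sparse field: neighbourhoods rarely overlap, so the pooled index
        # and neighbour-mean values are close to independent under the null
        spec = SpatialSimSpec(n_cells=500, field_size=(1000.0, 1000.0),
                              contact_effect=0.0, seed=7)
        tab, _ = kh.simulate_spatial(spec)
        summ = spatial_summaries(tab)
        rng = np.random.default_rng(0)
        sig = total = 0
        for _ in range(40):
            perm = tab.copy()
            perm["condition"] = rng.permutation(tab["condition"].to_numpy())
            comp = kh.compare_conditions(perm, summ, "opp")
            sig += int((comp["p"] < 0.05).sum())
            total += len(comp)
        assert sig / total <= 0.075

    def test_identical_distributions_d_zero(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 300, size=(400, 2))
        tg = rng.uniform(size=400) < 0.2
        opp = rng.lognormal(4, 0.3, 400)
        a = table_from_xy(xy, is_transgene=tg, condition="control", opp=opp)
        b = table_from_xy(xy, is_transgene=tg, condition="treated", opp=opp)
        b["cell_id"] = "t_" + b["cell_id"]
        tab = pd.concat([a, b], ignore_index=True)
        summ = spatial_summaries(tab)
        comp = kh.compare_conditions(tab, summ, "opp")
        np.testing.assert_allclose(comp["ks_statistic"], 0.0)


class TestMarkerStratifiedEdu:
    def test_all_edu_positive_degenerate(self):
        rng = np.random.default_rng(9)
        frames = []
        for cond in ("control", "treated"):
            for rep in ("r1", "r2"):
                xy = rng.uniform(0, 200, size=(100, 2))
                f = table_from_xy(xy, condition=cond, replicate=rep,
                                  bcl3_nuclear=rng.lognormal(4, 0.3, 100),
                                  edu_positive=True)
                f["cell_id"] = f"{cond}_{rep}_" + f["cell_id"]
                frames.append(f)
        tab = pd.concat(frames, ignore_index=True)
        per_rep, comp = kh.marker_stratified_edu(tab, "bcl3_nuclear")
        assert (per_rep["edu_fraction"] == 1.0).all()
        assert comp["t_p"].iloc[0] == 1.0

    def test_quantile_zero_reduces_to_overall_fraction(self):
        spec = SpatialSimSpec(n_cells=500, seed=10)
        tab, _ = kh.simulate_spatial(spec)
        cfg = kh.AnalysisConfig(tf_high_quantile=0.0)
        per_rep, _ = kh.marker_stratified_edu(tab, "bcl3_nuclear", cfg)
        wt = tab[~tab["is_transgene"]]
        overall = wt.groupby(["condition", "replicate"])["edu_positive"].mean()
        for _, row in per_rep.iterrows():
            assert row["edu_fraction"] == pytest.approx(
                overall.loc[(row["condition"], row["replicate"])]
            )

    def test_planted_boost_recovered(self):
        wins = 0
        n_runs = 50
        for seed in range(n_runs):
            spec = SpatialSimSpec(n_cells=2000, edu_contact_boost=0.15, seed=seed)
            tab, _ = kh.simulate_spatial(spec)
            _, comp = kh.marker_stratified_edu(tab, "bcl3_nuclear")
            row = comp.iloc[0]
            means = {row["condition_a"]: row["mean_a"], row["condition_b"]: row["mean_b"]}
            wins += means["treated"] > means["control"]
        assert wins / n_runs >= 0.9
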