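"""Mass-univariate statistics: rmANOVA oracles, adjacency, the
spatiotemporal cluster criterion, ROI windows, post hocs."""

import numpy as np
import pandas as pd
import pytest

from crterp.layout import ElectrodeLayout
from crterp.preprocess import EpochedERP
from crterp.stats import (
    StatMap,
    behavioral_rmanova,
    electrode_adjacency,
    pointwise_rmanova,
    posthoc_pairwise,
    rmanova_1way,
    roi_waveform_anova,
    spatiotemporal_cluster_filter,
)


def brute_force_rmanova(y):
    """Textbook two-way (subject x condition) sum-of-squares oracle."""
    n, c = y.shape
    grand = y.mean()
    ss_cond = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(c))
    ss_subj = sum(c * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (y[i, j] - y[:, j].mean() - y[i].mean() + grand) ** 2
        for i in range(n) for j in range(c)
    )
    return (ss_cond / (c - 1)) / (ss_err / ((n - 1) * (c - 1)))


class TestRmAnova:
    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20, 3))
        f, *_ = rmanova_1way(y[:, :, None])
        assert f[0] == pytest.approx(brute_force_rmanova(y), rel=1e-10)

    def test_matches_pingouin_including_gg_epsilon(self):
        import pingouin as pg

        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        f, p, d1, d2, eps = rmanova_1way(y[:, :, None])
        df = pd.DataFrame(
            [{"subject": s, "cond": c, "y": y[s, c]}
             for s in range(12) for c in range(4)]
        )
        aov = pg.rm_anova(data=df, dv="y", within="cond", subject="subject",
                          correction=True)
        row = aov.iloc[0]
        assert f[0] == pytest.approx(row["F"], rel=1e-8)
        assert eps[0] == pytest.approx(row["eps"], rel=1e-6)
        pg_p = row["p_GG_corr"] if "p_GG_corr" in row.index else row["p-GG-corr"]
        assert p[0] == pytest.approx(pg_p, rel=1e-6)

    def test_identical_conditions_give_zero_f(self):
        y = np.tile(np.random.default_rng(2).normal(size=(10, 1)), (1, 3))
        f, p, *_ = rmanova_1way(y[:, :, None])
        assert f[0] == pytest.approx(0.0, abs=1e-12) and p[0] > 0.999

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(20, 3, 4000))
        _, p, *_ = rmanova_1way(y)
        rate = (p < 0.005).mean()
        se = np.sqrt(0.005 * 0.995 / 4000)
        assert abs(rate - 0.005) < 3 * se

    def test_missing_cell_raises_named_error(self, study_erps):
        _, erps, _ = study_erps
        data = erps.data.copy()
        data[2, 1] = np.nan
        bad = EpochedERP(data, erps.srate, erps.window, erps.conditions,
                         erps.channel_labels, erps.n_epochs_accepted)
        with pytest.raises(ValueError, match="subject 2.*Rep3"):
            pointwise_rmanova(bad)


class TestAdjacency:
    def test_three_equidistant_fully_connected(self):
        pos = np.array([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                        [-0.5, -np.sqrt(3) / 2, 0]], dtype=float)
        lay = ElectrodeLayout(list("abc"), pos)
        adj = electrode_adjacency(lay, d=1.5)
        assert adj.sum() == 6

    def test_two_far_triads_form_two_components(self):
        import networkx as nx

        base = np.array([[1, 0, 0], [0.95, 0.2, 0], [0.95, -0.2, 0]])
        pos = np.vstack([base, -base])
        lay = ElectrodeLayout([f"e{i}" for i in range(6)], pos)
        adj = electrode_adjacency(lay, d=1.5)
        g = nx.from_numpy_array(adj)
        assert nx.number_connected_components(g) == 2

    def test_shipped_layout_mean_degree_in_expected_range(self, layout):
        adj = electrode_adjacency(layout)
        deg = adj.sum(axis=1).mean()
        assert 4 <= deg <= 10

    def test_delaunay_rule_symmetric_connected(self, layout):
        import networkx as nx

        adj = electrode_adjacency(layout, rule="delaunay")
        assert np.array_equal(adj, adj.T)
        assert nx.is_connected(nx.from_numpy_array(adj))


def _statmap_from_p(p, srate=512.0):
    return StatMap(F=np.zeros_like(p), p=p, df_num=None, df_den=None,
                   epsilon=None, srate=srate, window=(-50.0, 550.0))


def brute_force_clusters(p, adj, min_el, min_tp, alpha):
    """Independent enumerator built on networkx connected components."""
    import networkx as nx

    n_ch, n_t = p.shape
    g_sp = nx.from_numpy_array(adj)
    slices = []
    for t in range(n_t):
        members = [e for e in range(n_ch) if p[e, t] < alpha]
        sub = g_sp.subgraph(members)
        for comp in nx.connected_components(sub):
            if len(comp) >= min_el:
                slices.append((t, frozenset(comp)))
    g = nx.Graph()
    g.add_nodes_from(range(len(slices)))
    for i, (t1, c1) in enumerate(slices):
        for j, (t2, c2) in enumerate(slices):
            if t2 == t1 + 1 and c1 & c2:
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        ts = [slices[i][0] for i in comp]
        if max(ts) - min(ts) + 1 < min_tp:
            continue
        electrodes = sorted(set().union(*(slices[i][1] for i in comp)))
        out.append((min(ts), max(ts), tuple(electrodes)))
    return sorted(out)


class TestClusterFilter:
    def _toy_adj(self, toy_layout):
        return electrode_adjacency(toy_layout, d=2.0)

    def test_patch_below_electrode_minimum_discarded(self, toy_layout):
        adj = np.ones((20, 20), bool)
        np.fill_diagonal(adj, False)
        p = np.ones((20, 100))
        p[:9, :] = 1e-6
        cs = spatiotemporal_cluster_filter(_statmap_from_p(p), adj, 10, 15, 0.005)
        assert cs.clusters == []

    def test_patch_meeting_both_minima_is_one_cluster(self, toy_layout):
        adj = np.ones((20, 20), bool)
        np.fill_diagonal(adj, False)
        p = np.ones((20, 100))
        p[:12, 40:60] = 1e-6
        cs = spatiotemporal_cluster_filter(_statmap_from_p(p), adj, 10, 15, 0.005)
        assert len(cs.clusters) == 1
        c = cs.clusters[0]
        assert (c["t_start"], c["t_end"]) == (40, 59)
        assert c["electrodes"] == list(range(12))

    def test_equivalent_to_exhaustive_enumeration(self, toy_layout):
        rng = np.random.default_rng(0)
        adj = self._toy_adj(toy_layout)
        for _ in range(50):
            p = rng.random((20, 50)) ** 2  # enrich small p values
            alpha = rng.choice([0.05, 0.2, 0.4])
            min_el, min_tp = rng.integers(2, 6), rng.integers(2, 8)
            cs = spatiotemporal_cluster_filter(_statmap_from_p(p), adj,
                                               min_el, min_tp, alpha)
            mine = sorted((c["t_start"], c["t_end"], tuple(c["electrodes"]))
                          for c in cs.clusters)
            assert mine == brute_force_clusters(p, adj, min_el, min_tp, alpha)

    def test_monotone_in_criterion(self, toy_layout):
        rng = np.random.default_rng(1)
        adj = self._toy_adj(toy_layout)
        p = rng.random((20, 50)) ** 2
        strict = spatiotemporal_cluster_filter(_statmap_from_p(p), adj, 4, 6, 0.1)
        lax = spatiotemporal_cluster_filter(_statmap_from_p(p), adj, 3, 4, 0.2)
        for c in strict.clusters:
            assert any(
                set(c["electrodes"]) <= set(cl["electrodes"])
                and cl["t_start"] <= c["t_start"] and cl["t_end"] >= c["t_end"]
                for cl in lax.clusters
            )


class TestRoiAndPosthoc:
    def test_planted_window_recovered(self, study_erps, layout):
        _, erps, _ = study_erps
        wins = roi_waveform_anova(erps, layout.roi_sets["fronto_central"])
        assert any(w["start_ms"] < 215 and w["end_ms"] > 160 for w in wins)

    def test_identical_conditions_give_no_windows(self, layout):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(12, 1, 128, 307))
        data = np.repeat(one, 3, axis=1)
        erps = EpochedERP(data, 512.0, (-50.0, 550.0), ["a", "b", "c"],
                          layout.labels, np.ones((12, 3), int))
        assert roi_waveform_anova(erps, layout.labels[:16]) == []

    def test_run_shorter_than_30ms_excluded(self, layout):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(14, 3, 128, 307)) * 0.05
        data[:, 0, :, 100:113] += 5.0  # 13 samples = 25 ms < 30 ms
        erps = EpochedERP(data, 512.0, (-50.0, 550.0), ["a", "b", "c"],
                          layout.labels, np.ones((14, 3), int))
        wins = roi_waveform_anova(erps, layout.labels[:16])
        assert wins == []

    def test_unknown_roi_channel_raises(self, study_erps):
        _, erps, _ = study_erps
        with pytest.raises(ValueError, match="nope"):
            roi_waveform_anova(erps, ["nope"])

    def test_posthoc_directions_match_planted_contrast(self, study_erps, layout):
        truth, erps, _ = study_erps
        # in 405-470 ms NBack expresses map 2 more strongly
        res = posthoc_pairwise(erps, (405.0, 470.0),
                               electrodes=np.argsort(-np.abs(truth.templates.maps[2]))[:10])
        res = {r["pair"]: r for r in res}
        assert res[("New", "NBack")]["p"] < 0.01
        assert res[("New", "Rep3")]["p"] > res[("New", "NBack")]["p"]

    def test_posthoc_antisymmetry_and_identity(self, study_erps):
        _, erps, _ = study_erps
        res = {r["pair"]: r for r in posthoc_pairwise(erps, (145.0, 300.0))}
        flipped = EpochedERP(erps.data[:, ::-1], erps.srate, erps.window,
                             erps.conditions[::-1], erps.channel_labels,
                             erps.n_epochs_accepted)
        res_f = {r["pair"]: r for r in posthoc_pairwise(flipped, (145.0, 300.0))}
        t_ab = res[("New", "NBack")]["t"]
        t_ba = res_f[("NBack", "New")]["t"]
        assert t_ab == pytest.approx(-t_ba, rel=1e-12)
        # identical pair
        dup = EpochedERP(np.repeat(erps.data[:, :1], 2, axis=1), erps.srate,
                         erps.window, ["x", "y"], erps.channel_labels,
                         erps.n_epochs_accepted[:, :2])
        r = posthoc_pairwise(dup, (145.0, 300.0))[0]
        assert r["t"] == 0.0 and r["direction"] == 0


class TestBehavioral:
    def test_constant_table(self):
        res = behavioral_rmanova(np.full((10, 3), 0.9))
        assert res["F"] == 0.0 and res["partial_eta_sq"] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(loc=[500, 480, 460], scale=30, size=(20, 3))
        res = behavioral_rmanova(y)
        assert res["F"] == pytest.approx(brute_force_rmanova(y), rel=1e-10)
        assert 0 <= res["partial_eta_sq"] <= 1
        assert res["df_num"] <= 2 and res["df_den"] <= 38  # GG shrinks dfs

    def test_missing_cell_rejected(self):
        y = np.full((5, 3), 1.0)
        y[2, 1] = np.nan
        with pytest.raises(ValueError, match="subject 2"):
            behavioral_rmanova(y)
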