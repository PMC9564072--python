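"""Markers, PPI subnetworks, trend filter, drug mapping and screening."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from oncotraj import drugs as D
from oncotraj.sim import PATH_I, PATH_II, PRE
from oncotraj.trajectory import Trajectory


def _adata(x, genes):
    a = ad.AnnData(X=np.asarray(x, dtype=float))
    a.var_names = genes
    a.obs_names = [f"c{i}" for i in range(x.shape[0])]
    a.uns["layer"] = "lognorm"
    return a


class TestMarkers:
    def test_exclusive_gene_auroc_one(self, rng):
        x = np.zeros((40, 2))
        x[:20, 0] = 3.0
        x[:, 1] = rng.uniform(0, 1, 40)
        a = _adata(x, ["excl", "noise"])
        cl = pd.Series(np.r_[np.ones(20), np.full(20, 2)], index=a.obs_names)
        res = D.find_cluster_markers(a, cl)
        hit = res[(res.gene == "excl") & (res.cluster == 1)]
        assert len(hit) == 1 and hit.auroc.iloc[0] == pytest.approx(1.0)

    def test_null_genes_rarely_kept(self, rng):
        x = rng.normal(size=(200, 500))
        a = _adata(x, [f"g{j}" for j in range(500)])
        cl = pd.Series(rng.integers(1, 6, 200), index=a.obs_names)
        res = D.find_cluster_markers(a, cl)
        assert len(res) / 500 <= 0.001

    def test_auroc_matches_u_statistic_oracle(self, rng):
        """AUROC equals the exhaustive pairwise-comparison count U/(n1*n2)."""
        x = rng.normal(size=(12, 3))
        a = _adata(x, ["g0", "g1", "g2"])
        cl = pd.Series([1] * 5 + [2] * 7, index=a.obs_names)
        res = D.find_cluster_markers(a, cl, auroc_min=-1.0, p_max=1.1)
        for _, row in res.iterrows():
            j = int(row.gene[1])
            mask = (cl == row.cluster).to_numpy()
            xin, xout = x[mask, j], x[~mask, j]
            u = sum(
                1.0 if a_ > b_ else (0.5 if a_ == b_ else 0.0)
                for a_ in xin
                for b_ in xout
            )
            assert row.auroc == pytest.approx(u / (len(xin) * len(xout)), abs=1e-9)


class TestSubnetwork:
    def test_induced_edges_match_bruteforce(self, rng):
        genes = [f"g{i}" for i in range(10)]
        rows = []
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.uniform() < 0.4:
                    rows.append((genes[i], genes[j]))
        edges = pd.DataFrame(rows + [("g0", "zz")], columns=["gene_a", "gene_b"])
        chosen = genes[:6]
        g = D.build_ppi_subnetwork(chosen, edges)
        expect = {
            (a, b)
            for a, b in rows
            if a in chosen and b in chosen
        }
        assert {tuple(sorted(e)) for e in g.edges} == {
            tuple(sorted(e)) for e in expect
        }
        assert set(g.nodes) == set(chosen)  # isolates retained

    def test_self_loops_dropped_duplicates_merged(self):
        edges = pd.DataFrame(
            {"gene_a": ["a", "a", "a"], "gene_b": ["a", "b", "b"]}
        )
        with pytest.warns(UserWarning, match="self-loop"):
            g = D.build_ppi_subnetwork(["a", "b"], edges)
        assert g.number_of_edges() == 1

    def test_no_edges_empty_hub_set(self):
        g = D.build_ppi_subnetwork(["a", "b"], pd.DataFrame({"gene_a": [], "gene_b": []}))
        table = D.compute_centralities(g)
        assert D.select_hubs(table) == []


class TestTrendFilter:
    def _traj(self, n=40, rng=None):
        idx = [f"c{i}" for i in range(2 * n)]
        t = np.r_[np.linspace(8, 20, n), np.linspace(8, 20, n)]
        br = [PATH_I] * n + [PATH_II] * n
        return Trajectory(
            pseudotime=pd.Series(t, index=idx),
            branch=pd.Series(br, index=idx),
            graph=None,
            root_vertex=None,
        )

    def test_noiseless_opposite_trends_kept(self):
        traj = self._traj()
        t = traj.pseudotime.to_numpy()
        up_ii = np.where(traj.branch == PATH_II, t, -t)
        flat = np.ones_like(t)
        a = _adata(np.column_stack([up_ii, flat]), ["good", "flat"])
        kept = D.branch_trend_filter(["good", "flat"], a, traj)
        assert kept == ["good"]

    def test_null_genes_rarely_admitted(self, rng):
        traj = self._traj()
        x = rng.normal(size=(80, 200))
        a = _adata(x, [f"g{j}" for j in range(200)])
        kept = D.branch_trend_filter(list(a.var_names), a, traj)
        assert len(kept) / 200 <= 0.01


class TestMapDrugs:
    def test_empty_targets(self):
        table = pd.DataFrame(
            {"drug_id": ["d1"], "drug_name": ["x"], "target_gene": ["g1"]}
        )
        assert len(D.map_drugs([], table)) == 0

    def test_multi_target_ranked_first_and_join_oracle(self, rng):
        genes = [f"g{i}" for i in range(8)]
        rows = []
        for d in range(5):
            for g in rng.choice(genes, size=rng.integers(1, 5), replace=False):
                rows.append((f"d{d}", f"name{d}", g))
        rows += [("dBIG", "big", g) for g in genes]
        table = pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_gene"])
        targets = genes[:5]
        out = D.map_drugs(targets, table)
        assert out.drug_id.iloc[0] == "dBIG"
        # join count equals a brute-force nested loop
        for _, row in out.iterrows():
            expect = {
                g
                for d, _, g in rows
                if d == row.drug_id and g in set(targets)
            }
            assert set(row.targets) == expect


class TestSensitivity:
    def _ref(self, rng, n_lines=30, genes=None):
        genes = genes or [f"g{j}" for j in range(15)]
        x = rng.normal(0, 1, (n_lines, len(genes)))
        return pd.DataFrame(x, index=[f"L{i}" for i in range(n_lines)], columns=genes)

    def test_noiseless_linear_reference_interpolated(self, rng):
        genes = [f"g{j}" for j in range(15)]
        expr = self._ref(rng, genes=genes)
        w = np.zeros(15)
        w[0], w[3] = -1.0, 0.5
        resp = pd.DataFrame({"drug": expr.to_numpy() @ w}, index=expr.index)
        sc = _adata(rng.normal(0, 1, (50, 15)), genes)
        cl = pd.Series(np.r_[np.ones(25), np.full(25, 2)], index=sc.obs_names)
        out = D.predict_sensitivity(
            expr, resp, sc, cl, ridge_alphas=[1e-8]
        )
        mu, sd = expr.to_numpy().mean(0), expr.to_numpy().std(0)
        manual = (((sc.X - mu) / sd) * sd + mu) @ w  # = sc.X @ w
        assert out.overall.iloc[0] == pytest.approx(manual.mean(), abs=1e-4)

    def test_null_response_flat_cluster_means(self, rng):
        genes = [f"g{j}" for j in range(15)]
        expr = self._ref(rng, genes=genes)
        resp = pd.DataFrame({"drug": rng.normal(0, 1, 30)}, index=expr.index)
        sc = _adata(rng.normal(0, 1, (60, 15)), genes)
        cl = pd.Series(rng.integers(1, 4, 60), index=sc.obs_names)
        out = D.predict_sensitivity(expr, resp, sc, cl)
        cmeans = out[[c for c in out.columns if str(c).startswith("cluster_")]]
        assert (cmeans.sub(out.overall, axis=0).abs() < 0.5).all().all()

    def test_too_few_observations_skipped(self, rng):
        genes = [f"g{j}" for j in range(12)]
        expr = self._ref(rng, genes=genes)
        resp = pd.DataFrame(
            {"drug": [1.0, 2.0] + [np.nan] * 28}, index=expr.index
        )
        sc = _adata(rng.normal(0, 1, (10, 12)), genes)
        cl = pd.Series(np.ones(10), index=sc.obs_names)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = D.predict_sensitivity(expr, resp, sc, cl)
        assert len(out) == 0

    def test_shared_gene_floor(self, rng):
        expr = self._ref(rng, genes=[f"g{j}" for j in range(5)])
        resp = pd.DataFrame({"drug": rng.normal(size=30)}, index=expr.index)
        sc = _adata(rng.normal(size=(10, 5)), [f"g{j}" for j in range(5)])
        cl = pd.Series(np.ones(10), index=sc.obs_names)
        with pytest.raises(ValueError, match="shared genes"):
            D.predict_sensitivity(expr, resp, sc, cl)


class TestScreens:
    def _screens(self):
        return pd.DataFrame(
            {
                "drug_id": ["block", "up", "specific"],
                "overall": [-0.3, 0.2, -0.2],
                "cluster_1": [-0.1, 0.2, -0.4],
                "cluster_2": [-0.5, 0.2, -0.1],
                "path_i_mean": [-0.1, 0.2, -0.1],
                "path_ii_mean": [-0.5, 0.2, -0.4],
            }
        )

    def test_blocking_rules(self):
        out = D.screen_blocking(self._screens())
        assert out.set_index("drug_id").passes_blocking.to_dict() == {
            "block": True,
            "up": False,
            "specific": True,
        }

    def test_cluster_specific_rules(self):
        out = D.screen_cluster_specific(
            self._screens(), {"specific": [1], "up": [1], "block": [1]}
        )
        got = out.set_index("drug_id").passes_cluster_specific.to_dict()
        assert got["specific"] is True  # -0.4 < -0.1, overall < 0
        assert got["up"] is False  # overall positive
        assert got["block"] is False  # targeting mean -0.1 > -0.5

    def test_screens_pure_functions(self):
        s = self._screens()
        o1 = D.screen_blocking(s)
        o2 = D.screen_blocking(s)
        pd.testing.assert_frame_equal(o1, o2)


def test_planted_drugs_end_to_end(world):
    """The planted blocking and cluster-specific drugs pass their screens on
    generator output with the true trajectory."""
    from oncotraj.sim import simulate_drug_reference

    cfg, adata, truth, logn = world
    expr, resp, targets = simulate_drug_reference(truth, cfg)
    traj = truth.to_trajectory()
    screens = D.predict_sensitivity(expr, resp, logn, truth.cluster, traj=traj)
    bl = D.screen_blocking(screens).set_index("drug_id")
    assert bool(bl.loc["D001", "passes_blocking"])
    assert not bool(bl.loc["D003", "passes_blocking"])  # zero-effect drug
    spec_clusters = truth.effective_drugs["D002"]["clusters"]
    cs = D.screen_cluster_specific(screens, {"D002": spec_clusters}).set_index(
        "drug_id"
    )
    assert bool(cs.loc["D002", "passes_cluster_specific"])
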