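import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cshmmtf.model_core import ModelParameters, TreeTopology, CellAssignment, ExpressionMatrix
from cshmmtf.synthetic_data import make_ground_truth, simulate_expression
from cshmmtf.tf_assignment import (
    PathDEResult,
    TFTargetMap,
    assign_tf_start_time,
    assign_tfs_to_paths,
    estimate_alpha,
    filter_expressed_tfs,
    path_de_genes,
    select_path_tfs,
    tf_target_enrichment,
    tf_assignment_frame,
)


class TestFilterExpressedTFs:
    def _frame(self, tf_nonzero, n_cells=20):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(1, 2, size=(3, n_cells)),
            index=["g1", "TFlow", "TFok"],
            columns=[f"c{i}" for i in range(n_cells)],
        )
        df.loc["TFlow"] = 0.0
        df.loc["TFlow", df.columns[:tf_nonzero]] = 1.0
        return df

    def test_below_and_at_threshold(self):
        df = self._frame(tf_nonzero=3)  # 15% expressed
        assert filter_expressed_tfs(df, ["TFlow", "TFok"]) == ["TFok"]
        df = self._frame(tf_nonzero=4)  # exactly 20%: "less than 20%" removed only
        assert filter_expressed_tfs(df, ["TFlow", "TFok"]) == ["TFlow", "TFok"]

    def test_absent_tf_removed(self):
        df = self._frame(4)
        assert filter_expressed_tfs(df, ["TFmissing"]) == []

    def test_no_cells_is_error(self):
        with pytest.raises(ValueError):
            filter_expressed_tfs(pd.DataFrame(index=["g1"]), ["g1"])


class TestPathDEGenes:
    def test_identical_groups_yield_p_one(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(5, 10)), index=[f"g{i}" for i in range(5)])
        res = path_de_genes(a, a.copy())
        np.testing.assert_allclose(res.p_values, 1.0)
        assert res.de_genes == set()

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(2)
        genes = ["flat", "shifted"]
        a = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)]), index=genes
        )
        b = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, 20), rng.normal(0, 0.1, 20)]), index=genes
        )
        res = path_de_genes(a, b)
        assert res.p_values["shifted"] < 1e-10
        assert "shifted" in res.de_genes and "flat" not in res.de_genes

    def test_too_few_cells(self):
        a = pd.DataFrame(np.zeros((2, 1)), index=["g0", "g1"])
        b = pd.DataFrame(np.zeros((2, 5)), index=["g0", "g1"])
        with pytest.raises(ValueError, match="fewer than 2"):
            path_de_genes(a, b, path_id="p9")


def _enumerate_upper_tail(N, K, n, k):
    """Exact P(overlap >= k) by summing the hypergeometric pmf."""
    total = 0
    denom = math.comb(N, n)
    for j in range(k, min(n, K) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


class TestTFTargetEnrichment:
    def test_worked_example_one_third(self):
        universe = {f"g{i}" for i in range(10)}
        de = {"g0", "g1", "g2"}
        targets = TFTargetMap({"TF": {"g0", "g1", "g3", "g4"}})
        assert tf_target_enrichment(de, "TF", targets, universe) == pytest.approx(1 / 3)

    def test_zero_overlap_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        targets = TFTargetMap({"TF": {"g8", "g9"}})
        assert tf_target_enrichment({"g0"}, "TF", targets, universe) == pytest.approx(1.0)

    def test_no_targets_in_universe(self):
        targets = TFTargetMap({"TF": {"other"}})
        assert tf_target_enrichment({"g0"}, "TF", targets, {"g0", "g1"}) == 1.0

    def test_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            N = int(rng.integers(5, 30))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            tgt = set(rng.choice(sorted(universe), K, replace=False))
            de = set(rng.choice(sorted(universe), n, replace=False))
            k = len(tgt & de)
            expected = _enumerate_upper_tail(N, K, n, k)
            got = tf_target_enrichment(de, "TF", TFTargetMap({"TF": tgt}), universe)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_binomial_flag(self):
        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(10)}
        targets = TFTargetMap({"TF": {f"g{i}" for i in range(5, 25)}})
        k = len(targets.targets["TF"] & de)
        from scipy.stats import binom

        expected = float(binom.sf(k - 1, len(de), 20 / 100))
        got = tf_target_enrichment(de, "TF", targets, universe, method="binomial")
        assert got == pytest.approx(expected)


class TestSelectPathTFs:
    def test_cap_at_ten(self):
        pvals = {f"TF{i:02d}": 0.001 * (i + 1) for i in range(15)}
        kept = select_path_tfs(pvals)
        assert len(kept) == 10
        assert kept == [f"TF{i:02d}" for i in range(10)]

    def test_none_pass(self):
        assert select_path_tfs({"TFa": 0.2, "TFb": 0.9}) == []

    def test_tie_break_lexicographic(self):
        pvals = {"TFz": 0.01, "TFa": 0.01}
        assert select_path_tfs(pvals, max_tfs=1) == ["TFa"]


def _planted_profile_setup(ts_true, n_targets=30, sigma=0.05, n_cells=80, seed=0):
    rng = np.random.default_rng(seed)
    G = n_targets
    gene_ids = [f"g{i}" for i in range(G)]
    topo = TreeTopology(nodes=["A", "B"], root="A", paths={"p0": ("A", "B")})
    g_a = rng.normal(0, 1, G)
    g_b = g_a + rng.choice([-1.0, 1.0], G) * rng.uniform(1, 2, G)
    K = rng.uniform(2, 8, G)
    model = ModelParameters(
        topology=topo,
        g={"A": g_a, "B": g_b},
        K={"p0": K},
        sigma2=np.full(G, sigma**2),
        B={"A": {"p0": 1.0}},
        omega=pd.DataFrame(1, index=gene_ids, columns=["TF0"], dtype=int),
        phi=pd.DataFrame(-1.0, index=["p0"], columns=["TF0"]),
        lambda_g=1.0,
        gene_ids=gene_ids,
    )
    t = rng.uniform(0, 1, n_cells)
    t_eff = np.maximum(0.0, t - ts_true)
    mu = g_b[:, None] + (g_a - g_b)[:, None] * np.exp(-K[:, None] * t_eff[None, :])
    x = mu + rng.normal(0, sigma, mu.shape)
    expr = ExpressionMatrix(x, gene_ids, [f"c{i}" for i in range(n_cells)],
                            np.zeros(n_cells, dtype=int))
    asg = CellAssignment([f"c{i}" for i in range(n_cells)],
                         np.array(["p0"] * n_cells, dtype=object), t)
    tmap = TFTargetMap({"TF0": set(gene_ids)})
    return model, expr, asg, tmap


class TestAssignTFStartTime:
    @pytest.mark.parametrize("ts_true", [0.0, 0.3])
    def test_recovers_planted_onset(self, ts_true):
        model, expr, asg, tmap = _planted_profile_setup(ts_true)
        assert assign_tf_start_time("TF0", "p0", model, expr, asg, tmap) == pytest.approx(
            ts_true
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_within_one_grid_step(self, seed):
        ts_true = float(np.random.default_rng(seed).choice(np.arange(0, 0.55, 0.05)))
        model, expr, asg, tmap = _planted_profile_setup(ts_true, sigma=0.1, seed=seed)
        got = assign_tf_start_time("TF0", "p0", model, expr, asg, tmap)
        assert abs(got - ts_true) <= 0.05 + 1e-12
        assert 0.0 <= got <= 0.5

    def test_no_targets_error(self):
        model, expr, asg, _ = _planted_profile_setup(0.0)
        with pytest.raises(ValueError, match="no targets"):
            assign_tf_start_time("TF0", "p0", model, expr, asg, TFTargetMap({"TF0": set()}))


class TestEstimateAlpha:
    def _de(self, genes, de_set):
        return PathDEResult(
            "p0",
            pd.Series([0.01 if g in de_set else 0.5 for g in genes], index=genes),
        )

    def test_constant_features_give_de_fraction(self):
        genes = [f"g{i}" for i in range(10)]
        de = self._de(genes, set(genes[:3]))
        alpha = estimate_alpha("p0", [], TFTargetMap({}), de)
        np.testing.assert_allclose(alpha.to_numpy(), 0.3)

    def test_separable_is_monotone(self):
        genes = [f"g{i}" for i in range(40)]
        targets = set(genes[:20])
        de = self._de(genes, targets)  # targets <=> DE, perfectly separable
        alpha = estimate_alpha("p0", ["TF0"], TFTargetMap({"TF0": targets}), de)
        assert alpha[genes[0]] > 0.9
        assert alpha[genes[-1]] < 0.1
        assert ((alpha >= 0) & (alpha <= 1)).all()

    def test_degenerate_labels(self):
        genes = [f"g{i}" for i in range(5)]
        de = self._de(genes, set(genes))
        alpha = estimate_alpha("p0", [], TFTargetMap({}), de)
        np.testing.assert_allclose(alpha.to_numpy(), 1.0)


class TestPlantedRegulonRecovery:
    def test_planted_tf_ranks_first_and_noise_paths_stay_nominal(self):
        """A TF with 50 targets changed only on a terminal path should top
        that path's ranking; sibling/parent paths (whose DE baseline does
        not contain the regulon) should flag it at no more than the
        nominal 5% rate of the raw per-path cutoff."""
        n_reps = 20
        rank_first = 0
        noise_hits = 0
        noise_tests = 0
        for rep in range(n_reps):
            truth = make_ground_truth(
                n_genes=300, n_tfs=1, topology_spec="two_split",
                targets_per_tf=50, seed=400 + rep, tf_paths=["p4"],
            )
            expr, asg = simulate_expression(truth, 40, seed=400 + rep)
            tfas = assign_tfs_to_paths(expr, truth.model, asg, truth.tf_targets)
            planted = truth.true_tf_times[0]
            on_path = [t for t in tfas if t.path_id == planted.path_id]
            if on_path and on_path[0].tf_id == planted.tf_id:
                rank_first += 1
            # pure-noise paths: not the planted path, not an ancestor of it,
            # and not the root (whose baseline spans all off-path cells)
            chain = set(truth.model.topology.root_chain(planted.path_id))
            noise_paths = [
                p for p in truth.model.topology.path_ids
                if p not in chain and truth.model.topology.parent_path(p) is not None
            ]
            noise_tests += len(noise_paths)
            noise_hits += sum(
                1 for t in tfas if t.path_id in noise_paths
            )
        assert rank_first >= 19
        # nominal alpha = 0.05: Binomial(n_tests, .05) 99.9th pct ~ 9 at n=60
        assert noise_hits <= 9, f"{noise_hits} false path hits in {noise_tests} tests"


class TestAssignmentFrame:
    def test_direction_is_sign_of_target_change(self, fork_truth):
        truth, expr, asg = fork_truth
        tfas = assign_tfs_to_paths(expr, truth.model, asg, truth.tf_targets)
        frame = tf_assignment_frame(tfas, truth.model)
        assert set(frame.columns) >= {"path_id", "tf_id", "t_start", "p_value",
                                      "direction"}
        gene_idx = {g: i for i, g in enumerate(truth.model.gene_ids)}
        for row in frame.itertuples():
            targets = [gene_idx[g] for g in truth.tf_targets.targets[row.tf_id]]
            mean_dg = truth.model.delta_g(row.path_id)[targets].mean()
            assert row.direction == ("activator" if mean_dg >= 0 else "repressor")
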