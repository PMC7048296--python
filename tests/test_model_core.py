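import json
import math

import numpy as np
import pandas as pd
import pytest

from cshmmtf.model_core import (
    CellAssignment,
    ExpressionMatrix,
    TreeTopology,
    cell_state_log_score,
    emission_log_density,
    emission_mean,
    model_from_json,
    model_to_json,
    path_prior_log_prob,
    penalized_log_likelihood,
    resolve_gene_t_start,
    validate_model,
    TFAssignment,
)
from conftest import (
    assignment_on,
    expression_from_values,
    make_chain_model,
    make_fork_model,
)

LOG_2PI = math.log(2 * math.pi)


class TestEmissionMean:
    @pytest.mark.parametrize(
        "g_a,g_b,K,t,t_start,expected",
        [
            (2.0, 0.0, 1.0, 0.0, 0.0, 2.0),  # exp(0) = 1 forces mu = g_a
            (2.0, 0.0, 1.0, 0.3, 0.5, 2.0),  # t <= t_start => effective time 0
            (2.0, 0.0, 1.0, 1.0, 0.0, 2.0 * math.exp(-1.0)),
            (1.0, 3.0, 2.0, 0.75, 0.25, 3.0 - 2.0 * math.exp(-1.0)),
        ],
    )
    def test_closed_form(self, g_a, g_b, K, t, t_start, expected):
        assert emission_mean(g_a, g_b, K, t, t_start) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            emission_mean(1.0, 0.0, -0.5, 0.5, 0.0)
        with pytest.raises(ValueError):
            emission_mean(1.0, 0.0, 1.0, 1.2, 0.0)

    def test_no_tf_case_equals_t_start_zero(self):
        rng = np.random.default_rng(0)
        g_a, g_b = rng.normal(size=20), rng.normal(size=20)
        K, t = rng.uniform(0, 10, 20), rng.uniform(0, 1, 20)
        np.testing.assert_allclose(
            emission_mean(g_a, g_b, K, t, None),
            emission_mean(g_a, g_b, K, t, np.zeros(20)),
        )

    def test_monotone_and_bounded_in_t(self):
        t = np.linspace(0, 1, 101)
        for g_a, g_b, K, ts in [(2, 0, 3, 0.0), (0, 5, 0.7, 0.2), (-1, -4, 10, 0.5)]:
            mu = emission_mean(g_a, g_b, K, t, ts)
            assert mu[0] == pytest.approx(g_a)
            diffs = np.diff(mu)
            assert np.all(diffs <= 1e-12) or np.all(diffs >= -1e-12)
            assert np.all(mu >= min(g_a, g_b) - 1e-12)
            assert np.all(mu <= max(g_a, g_b) + 1e-12)


class TestEmissionLogDensity:
    def test_standard_normal_at_mode(self):
        assert emission_log_density(0.0, 0.0, 1.0) == pytest.approx(-0.5 * LOG_2PI)

    def test_one_sigma_away(self):
        assert emission_log_density(1.0, 0.0, 1.0) == pytest.approx(-0.5 * LOG_2PI - 0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mu, d, s2 = rng.normal(), rng.uniform(0.1, 3), rng.uniform(0.1, 4)
            assert emission_log_density(mu + d, mu, s2) == pytest.approx(
                emission_log_density(mu - d, mu, s2)
            )

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            emission_log_density(0.0, 0.0, 0.0)

    @pytest.mark.parametrize("mu,s2", [(0.0, 1.0), (2.5, 0.3), (-1.0, 4.0)])
    def test_integrates_to_one(self, mu, s2):
        x = np.linspace(mu - 12 * math.sqrt(s2), mu + 12 * math.sqrt(s2), 40001)
        total = np.trapezoid(np.exp(emission_log_density(x, mu, s2)), x)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestPathPrior:
    def test_root_path_is_zero(self, chain_model):
        assert path_prior_log_prob("p0", chain_model) == 0.0

    def test_two_splits_half_each(self):
        topo = TreeTopology(
            nodes=["D0", "D1", "D2", "D3", "D4", "D5"],
            root="D0",
            paths={
                "p0": ("D0", "D1"),
                "p1": ("D1", "D2"),
                "p2": ("D1", "D3"),
                "p3": ("D2", "D4"),
                "p4": ("D2", "D5"),
            },
        )
        model = make_chain_model()
        model.topology = topo
        model.B = {
            "D0": {"p0": 1.0},
            "D1": {"p1": 0.5, "p2": 0.5},
            "D2": {"p3": 0.5, "p4": 0.5},
        }
        assert path_prior_log_prob("p3", model) == pytest.approx(math.log(0.25))

    def test_depth_monotone(self, fork_model):
        assert path_prior_log_prob("p1", fork_model) < path_prior_log_prob(
            "p0", fork_model
        )

    def test_unknown_path(self, chain_model):
        with pytest.raises(KeyError):
            path_prior_log_prob("nope", chain_model)


class TestCellStateLogScore:
    def test_zero_residual_root(self):
        model = make_chain_model(n_genes=1)
        x = model.g["D0"].copy()  # equals mean at (p0, t=0)
        score = cell_state_log_score(x, ("p0", 0.0), model)
        # sigma2 = 0.5: -0.5*log(2*pi*0.5)
        assert score == pytest.approx(-0.5 * math.log(2 * math.pi * 0.5))

    def test_decomposition(self, fork_model):
        rng = np.random.default_rng(2)
        x = rng.normal(size=fork_model.n_genes)
        state = ("p1", 0.4)
        ts = resolve_gene_t_start(fork_model, "p1")
        expected = sum(
            emission_log_density(
                x[j],
                emission_mean(
                    fork_model.g["D1"][j],
                    fork_model.g["D2"][j],
                    fork_model.K["p1"][j],
                    0.4,
                    ts[j],
                ),
                fork_model.sigma2[j],
            )
            for j in range(fork_model.n_genes)
        ) + path_prior_log_prob("p1", fork_model)
        assert cell_state_log_score(x, state, fork_model) == pytest.approx(expected)

    def test_grid_argmax_recovers_generating_state(self):
        model = make_fork_model(n_genes=5)
        model.sigma2 = np.full(5, 1e-6)
        t_true, p_true = 0.37, "p1"
        mu = [
            emission_mean(model.g["D1"][j], model.g["D2"][j], 2.0, t_true, 0.0)
            for j in range(5)
        ]
        grid = np.linspace(0, 1, 101)
        best = max(
            ((p, t) for p in model.topology.path_ids for t in grid),
            key=lambda s: cell_state_log_score(np.array(mu), s, model),
        )
        assert best == (p_true, pytest.approx(t_true))

    def test_dimension_mismatch(self, chain_model):
        with pytest.raises(ValueError):
            cell_state_log_score(np.zeros(99), ("p0", 0.0), chain_model)


class TestPenalizedLogLikelihood:
    def test_no_cells_no_change_is_zero(self):
        model = make_chain_model(n_genes=2)
        for nd in model.g:
            model.g[nd] = np.zeros(2)  # delta g = 0 on every path
        data = expression_from_values(np.zeros((2, 0)))
        asg = assignment_on([], [])
        assert penalized_log_likelihood(data, asg, model) == 0.0

    def test_penalty_scaling_with_alpha(self):
        model = make_chain_model(n_genes=1)
        model.g = {"D0": np.zeros(1), "D1": np.ones(1), "D2": np.ones(1)}
        data = expression_from_values(np.zeros((1, 0)))
        asg = assignment_on([], [])
        # |delta g| = 1 on p0 only; lambda = 1
        assert penalized_log_likelihood(data, asg, model) == pytest.approx(-1.0)
        alpha = {"p0": np.ones(1), "p1": np.zeros(1)}
        assert penalized_log_likelihood(data, asg, model, alpha=alpha) == pytest.approx(
            -0.5
        )

    def test_term_by_term_on_three_cells(self, fork_model):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(fork_model.n_genes, 3))
        data = expression_from_values(x)
        asg = assignment_on(["p0", "p1", "p2"], [0.2, 0.5, 0.9])
        expected = sum(
            cell_state_log_score(x[:, i], (asg.path_ids[i], asg.times[i]), fork_model)
            for i in range(3)
        ) - sum(
            fork_model.lambda_g * np.sum(np.abs(fork_model.delta_g(p)))
            for p in fork_model.topology.path_ids
        )
        assert penalized_log_likelihood(data, asg, fork_model) == pytest.approx(expected)

    def test_strictly_decreasing_in_lambda(self, fork_model):
        data = expression_from_values(np.zeros((fork_model.n_genes, 1)))
        asg = assignment_on(["p0"], [0.0])
        lo = penalized_log_likelihood(data, asg, fork_model)
        fork_model.lambda_g = 5.0
        hi = penalized_log_likelihood(data, asg, fork_model)
        assert hi < lo


class TestValidateModel:
    def test_valid_model_clean(self, chain_model, fork_model):
        assert validate_model(chain_model) == []
        assert validate_model(fork_model) == []

    def test_unnormalized_branch_row(self, fork_model):
        fork_model.B["D1"] = {"p1": 0.5, "p2": 0.4}
        problems = validate_model(fork_model)
        assert any("D1" in p and "sum" in p for p in problems)

    def test_phi_bound(self, chain_model):
        chain_model.phi.loc["p0", "TFa"] = 0.7
        assert any("phi" in p for p in validate_model(chain_model))


class TestSerialization:
    def test_round_trip(self, fork_model):
        fork_model.phi["TFx"] = -1.0
        fork_model.omega = pd.DataFrame(
            0, index=fork_model.gene_ids, columns=["TFx"], dtype=int
        )
        fork_model.omega.iloc[0, 0] = 1
        fork_model.g["D1"][0] = 1 / 3  # non-terminating binary fraction round-trips
        text = model_to_json(fork_model)
        back = model_from_json(text)
        assert back.topology.paths == fork_model.topology.paths
        assert back.topology.root == fork_model.topology.root
        for nd in fork_model.g:
            np.testing.assert_array_equal(back.g[nd], fork_model.g[nd])
        for p in fork_model.K:
            np.testing.assert_array_equal(back.K[p], fork_model.K[p])
        np.testing.assert_array_equal(back.sigma2, fork_model.sigma2)
        assert back.B == fork_model.B
        pd.testing.assert_frame_equal(
            back.omega, fork_model.omega, check_dtype=False
        )
        assert validate_model(back) == []
        # serialization is deterministic
        assert model_to_json(back) == text


class TestDomainTypes:
    def test_expression_matrix_rejects_bad_input(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(np.zeros((2, 1)), ["g", "g"], ["c"], [0])
        with pytest.raises(ValueError, match="finite"):
            ExpressionMatrix(np.array([[np.nan]]), ["g"], ["c"], [0])
        with pytest.raises(ValueError):
            ExpressionMatrix(np.zeros((2, 3)), ["a", "b"], ["c1", "c2"], [0, 0])

    def test_topology_rejects_double_incoming(self):
        with pytest.raises(ValueError, match="more than one incoming"):
            TreeTopology(
                nodes=["D0", "D1", "D2"],
                root="D0",
                paths={"p0": ("D0", "D1"), "p1": ("D0", "D1")},
            )

    def test_topology_chain_queries(self, fork_model):
        topo = fork_model.topology
        assert topo.root_chain("p1") == ["p0", "p1"]
        assert topo.parent_path("p1") == "p0"
        assert topo.parent_path("p0") is None
        assert topo.on_same_chain("p0", "p2")
        assert not topo.on_same_chain("p1", "p2")
        assert topo.path_depth("p2") == 1

    def test_assignment_bounds(self):
        with pytest.raises(ValueError):
            CellAssignment(["c0"], np.array(["p0"], dtype=object), np.array([1.5]))

    def test_tf_assignment_bounds(self):
        with pytest.raises(ValueError):
            TFAssignment("p0", "TF1", 0.7, 0.01, 5)
        assert TFAssignment("p0", "TF1", 0.0, 0.01, 5).is_early
        assert not TFAssignment("p0", "TF1", 0.05, 0.01, 5).is_early

    def test_earliest_regulator_wins(self):
        model = make_chain_model(n_genes=3)
        model.omega = pd.DataFrame(
            [[1, 1], [1, 0], [0, 0]], index=model.gene_ids, columns=["TFa", "TFb"]
        )
        tfas = [
            TFAssignment("p0", "TFa", 0.4, 0.01, 2),
            TFAssignment("p0", "TFb", 0.1, 0.01, 1),
        ]
        ts = resolve_gene_t_start(model, "p0", tfas)
        # gene 0 targeted by both: earliest activation (0.1) applies
        np.testing.assert_allclose(ts, [0.1, 0.4, 0.0])
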