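"""Nodewise estimation, EBIC selection, aggregation, predictability, moderation."""

import numpy as np
import pandas as pd
import pytest

from mgmnet import (
    EstimatorConfig,
    MixedDataset,
    VariableSpec,
    aggregate_network,
    ebic_score,
    estimate_mgm,
    fit_moderated,
    fit_nodewise,
    make_planted_model,
    predictability,
    sample_mgm,
    standardize_continuous,
    true_partial_correlations,
)
from mgmnet.mgm import NodewiseFit


class TestEbicScore:
    def test_gamma_zero_is_bic(self):
        assert ebic_score(-10.0, 2, 100, 5, 0.0) == pytest.approx(
            20.0 + 2 * np.log(100)
        )

    def test_worked_arithmetic(self):
        # 300 + 3·ln(100) + 1.5·ln(29)
        assert ebic_score(-150.0, 3, 100, 29, 0.25) == pytest.approx(318.87, abs=0.01)

    def test_df_zero_no_penalty(self):
        assert ebic_score(-7.5, 0, 50, 10, 0.25) == pytest.approx(15.0)


def _gaussian_dataset(n, corr, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = corr * x + np.sqrt(1 - corr**2) * rng.standard_normal(n)
    specs = (VariableSpec("x", "continuous"), VariableSpec("y", "continuous"))
    ds = MixedDataset(pd.DataFrame({"x": x, "y": y}), specs)
    std, _ = standardize_continuous(ds)
    return std


class TestFitNodewise:
    def test_null_data_selects_empty_model(self):
        hits = 0
        for seed in range(10):
            model = make_planted_model(5, [], [], 0.0, 0.0, n_isolated=5, seed=seed)
            ds = sample_mgm(model, n=2000, seed=seed + 100)
            std, _ = standardize_continuous(ds)
            fit = fit_nodewise(std, "V01")
            hits += fit.df == 0
        assert hits >= 9

    def test_two_node_coefficient_recovers_partial(self):
        std = _gaussian_dataset(5000, 0.5, seed=3)
        fit = fit_nodewise(std, "y", lambda_grid=[1e-4])
        assert fit.coefficients["x"] == pytest.approx(0.5, abs=0.03)

    def test_lambda_max_gives_empty_fit(self):
        std = _gaussian_dataset(1000, 0.5, seed=4)
        fit = fit_nodewise(std, "y")
        # largest grid value is λ_max by construction: refit there
        empty = fit_nodewise(std, "y", lambda_grid=[fit.lambda_grid[0]])
        assert empty.df == 0

    def test_zero_variance_predictor_rejected(self):
        specs = (VariableSpec("x", "continuous"), VariableSpec("y", "continuous"))
        ds = MixedDataset(
            pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [0.0, 1.0, 2.0]}), specs
        )
        with pytest.raises(ValueError, match="zero-variance"):
            fit_nodewise(ds, "y")

    def test_gamma_monotone_in_edge_count(self, two_block_model):
        ds = sample_mgm(two_block_model, n=800, seed=42)
        counts = []
        for gamma in (0.0, 0.25, 0.5, 1.0):
            net, _ = estimate_mgm(ds, EstimatorConfig(gamma=gamma))
            counts.append(int((net.magnitude > 0).sum()) // 2)
        assert counts == sorted(counts, reverse=True)


def _fake_fit(node, coef_map, all_nodes, kinds):
    """Minimal gaussian/1-term NodewiseFit for aggregation unit tests."""
    terms = [n for n in all_nodes if n != node]
    coef = np.array([coef_map.get(t, 0.0) for t in terms])
    return NodewiseFit(
        node=node,
        kind="gaussian" if kinds[node] == "continuous" else "categorical",
        lambda_grid=np.array([0.1]),
        selected_lambda=0.1,
        coef=coef,
        intercept=np.zeros(1),
        terms=tuple(terms),
        term_var=tuple(terms),
        term_is_mod=np.zeros(len(terms), dtype=bool),
        loglik=0.0,
        df=int((coef != 0).sum()),
        ebic=0.0,
        ebic_path=np.array([0.0]),
        fitted=np.zeros(2),
        y=np.zeros(2),
        n=2,
        q=len(terms),
    )


class TestAggregation:
    specs = (
        VariableSpec("a", "continuous"),
        VariableSpec("b", "continuous"),
        VariableSpec("c", "categorical", levels=("0", "1")),
    )
    kinds = {"a": "continuous", "b": "continuous", "c": "categorical"}

    def _fits(self, ab, ba, ac=0.0, ca=0.0):
        nodes = ("a", "b", "c")
        return {
            "a": _fake_fit("a", {"b": ab, "c": ac}, nodes, self.kinds),
            "b": _fake_fit("b", {"a": ba}, nodes, self.kinds),
            "c": _fake_fit("c", {"a": ca}, nodes, self.kinds),
        }

    def test_and_rule_mean_and_sign(self):
        net = aggregate_network(self._fits(0.20, 0.30), self.specs, rule="AND")
        assert net.magnitude[0, 1] == pytest.approx(0.25)
        assert net.sign[0, 1] == 1

    def test_and_rule_zero_direction_kills_edge(self):
        net = aggregate_network(self._fits(0.20, 0.0), self.specs, rule="AND")
        assert net.magnitude[0, 1] == 0.0

    def test_or_rule_keeps_single_direction(self):
        net = aggregate_network(self._fits(0.20, 0.0), self.specs, rule="OR")
        assert net.magnitude[0, 1] == pytest.approx(0.20)
        assert net.sign[0, 1] == 0  # no agreeing pair of coefficients

    def test_disagreeing_signs_undefined(self):
        net = aggregate_network(self._fits(0.20, -0.30), self.specs, rule="AND")
        assert net.magnitude[0, 1] == pytest.approx(0.25)
        assert net.sign[0, 1] == 0

    def test_categorical_edge_never_signed(self):
        net = aggregate_network(
            self._fits(0.0, 0.0, ac=0.4, ca=0.4), self.specs, rule="AND"
        )
        assert net.magnitude[0, 2] > 0
        assert net.sign[0, 2] == 0
        assert net.involves_categorical[0, 2]

    def test_and_is_subset_of_or(self, two_block_data):
        std, _ = standardize_continuous(two_block_data)
        fits = {s.name: fit_nodewise(std, s.name) for s in std.specs}
        net_and = aggregate_network(fits, std.specs, rule="AND")
        net_or = aggregate_network(fits, std.specs, rule="OR")
        assert np.all((net_and.magnitude > 0) <= (net_or.magnitude > 0))

    def test_column_permutation_equivariance(self, two_block_data):
        net, _ = estimate_mgm(two_block_data)
        perm = [3, 0, 5, 1, 4, 2]
        names = [two_block_data.names[i] for i in perm]
        specs = tuple(two_block_data.spec(n) for n in names)
        permuted = MixedDataset(two_block_data.values[names].copy(), specs)
        net_p, _ = estimate_mgm(permuted)
        # equal up to the coordinate-descent solver tolerance
        np.testing.assert_allclose(
            net_p.magnitude, net.magnitude[np.ix_(perm, perm)], atol=1e-5
        )


class TestPredictability:
    def test_r2_equals_squared_coefficient(self):
        std = _gaussian_dataset(5000, 0.8, seed=6)
        fits = {s.name: fit_nodewise(std, s.name) for s in std.specs}
        report = predictability(std, fits)
        assert report.r2["y"] == pytest.approx(0.64, abs=0.03)

    def test_isolated_node_near_zero_r2(self):
        model = make_planted_model(3, [], [2], 0.4, 0.0, n_isolated=1, seed=7)
        ds = sample_mgm(model, n=2000, seed=8)
        _, fits = estimate_mgm(ds)
        report = predictability(ds, fits)
        assert report.r2["V03"] <= 0.02

    def test_empty_neighborhood_accuracy_is_mode_baseline(self):
        model = make_planted_model(2, [3], [2], 0.3, 0.0, n_isolated=1, seed=9)
        ds = sample_mgm(model, n=1500, seed=10)
        _, fits = estimate_mgm(ds)
        report = predictability(ds, fits)
        assert fits["C1"].df == 0
        assert report.accuracy["C1"] == pytest.approx(report.baseline["C1"])


class TestModerated:
    def test_constant_moderator_rejected(self):
        specs = tuple(VariableSpec(n, "continuous") for n in "xyz")
        table = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [1.0, 0.0, 1.0], "z": [2.0, 2.0, 2.0]}
        )
        with pytest.raises(ValueError, match="constant|zero variance"):
            fit_moderated(MixedDataset(table, specs), "z")

    def test_categorical_moderator_rejected(self, tiny_mixed):
        with pytest.raises(ValueError, match="categorical moderator"):
            fit_moderated(tiny_mixed, "g")

    def test_moderator_row_zeroed(self, two_block_data):
        std, _ = standardize_continuous(two_block_data)
        mod = fit_moderated(std, "V01", n_lambdas=20)
        m = mod.base.index("V01")
        assert np.all(mod.moderation_magnitude[m] == 0)


class TestNetworkStructure:
    def test_symmetry_zero_diagonal(self, two_block_data):
        net, _ = estimate_mgm(two_block_data)
        assert np.allclose(net.magnitude, net.magnitude.T)
        assert np.all(np.diag(net.magnitude) == 0)
        assert np.allclose(net.sign, net.sign.T)

    def test_oracle_magnitudes_at_weakest_lambda(self, two_block_model):
        ds = sample_mgm(two_block_model, n=5000, seed=33)
        std, _ = standardize_continuous(ds)
        fits = {
            s.name: fit_nodewise(std, s.name, lambda_grid=[1e-4]) for s in std.specs
        }
        net = aggregate_network(fits, std.specs, rule="AND")
        rho = np.abs(true_partial_correlations(two_block_model))
        np.fill_diagonal(rho, 0.0)
        np.testing.assert_allclose(net.magnitude, rho, atol=0.05)
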