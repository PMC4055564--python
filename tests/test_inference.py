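"""Parameter fitting and exact prediction against oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from cgbn.inference import (
    fit_parameters,
    joint_log_density,
    predict,
    predict_dataset,
)
from cgbn.model import (
    CGBayesNet,
    CLGNodeParams,
    DAGStructure,
    DiscreteNodeParams,
    MixedDataset,
    VariableSpec,
)
from cgbn.scoring import PriorHyper
from cgbn.simulate import GeneratorConfig, random_cgbn, sample_dataset

from oracles import dense_predict


class TestFitParameters:
    def test_parentless_binary_posterior_mean_cpt(self):
        specs = [VariableSpec("y", "discrete", ("1", "2"))]
        data = MixedDataset(pd.DataFrame({"y": ["1", "1", "1", "2"]}), specs, "y")
        net = fit_parameters(DAGStructure(["y"]), data, PriorHyper(alpha=2.0))
        cpt = net.params["y"].cpt
        assert cpt[0] == pytest.approx([4.0 / 6.0, 2.0 / 6.0], abs=1e-12)

    def test_continuous_consistency_at_large_n(self):
        rng = np.random.default_rng(0)
        n = 20000
        y = rng.normal(5.0, 2.0, n)
        specs = [VariableSpec("y", "continuous"), VariableSpec("phenotype", "discrete", ("a",))]
        data = MixedDataset(pd.DataFrame({"y": y, "phenotype": ["a"] * n}), specs, "phenotype")
        g = DAGStructure(["y", "phenotype"])
        net = fit_parameters(g, data, PriorHyper())
        p = net.params["y"]
        # 3 standard errors of the mean and of the variance estimate
        assert abs(p.intercepts[0] - 5.0) < 3 * 2.0 / np.sqrt(n)
        assert abs(p.variances[0] - 4.0) < 3 * 4.0 * np.sqrt(2.0 / n)

    def test_empty_configuration_falls_back_to_prior(self):
        # parent state "c" never observed alongside the child data
        specs = [
            VariableSpec("p", "discrete", ("a", "b", "c")),
            VariableSpec("d", "discrete", ("0", "1")),
            VariableSpec("x", "continuous"),
        ]
        frame = pd.DataFrame({"p": ["a", "a", "b"], "d": ["0", "1", "0"], "x": [1.0, 2.0, 3.0]})
        data = MixedDataset(frame, specs, "p")
        g = DAGStructure(["p", "d", "x"], [("p", "d"), ("p", "x")])
        prior = PriorHyper(sigma0_sq=1.5)
        net = fit_parameters(g, data, prior)
        assert net.params["d"].cpt[2] == pytest.approx([0.5, 0.5])
        assert net.params["x"].intercepts[2] == 0.0
        assert net.params["x"].variances[2] == pytest.approx(1.5)

    def test_recovers_regression_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 5000)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 5000)
        specs = [
            VariableSpec("x", "continuous"),
            VariableSpec("y", "continuous"),
            VariableSpec("phenotype", "discrete", ("a",)),
        ]
        data = MixedDataset(
            pd.DataFrame({"x": x, "y": y, "phenotype": ["a"] * 5000}), specs, "phenotype"
        )
        g = DAGStructure(["x", "y", "phenotype"], [("x", "y")])
        net = fit_parameters(g, data, PriorHyper())
        p = net.params["y"]
        assert p.coefs[0, 0] == pytest.approx(2.0, abs=0.05)
        assert p.intercepts[0] == pytest.approx(1.0, abs=0.05)
        assert p.variances[0] == pytest.approx(0.25, rel=0.1)


class TestJointLogDensity:
    def test_single_discrete_node(self):
        vs = (VariableSpec("d", "discrete", ("1", "2")),)
        net = CGBayesNet(
            DAGStructure(["d"]),
            vs,
            {"d": DiscreteNodeParams((), ("1", "2"), np.array([[0.25, 0.75]]))},
        )
        assert joint_log_density(net, {"d": "2"}) == pytest.approx(np.log(0.75))

    def test_standard_normal_node(self):
        vs = (VariableSpec("x", "continuous"), VariableSpec("d", "discrete", ("1",)))
        net = CGBayesNet(
            DAGStructure(["x", "d"]),
            vs,
            {
                "x": CLGNodeParams((), (), np.array([0.0]), np.zeros((1, 0)), np.array([1.0])),
                "d": DiscreteNodeParams((), ("1",), np.array([[1.0]])),
            },
        )
        assert joint_log_density(net, {"x": 0.0, "d": "1"}) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_missing_assignment_raises(self):
        vs = (VariableSpec("d", "discrete", ("1", "2")),)
        net = CGBayesNet(
            DAGStructure(["d"]),
            vs,
            {"d": DiscreteNodeParams((), ("1", "2"), np.array([[0.5, 0.5]]))},
        )
        with pytest.raises(ValueError):
            joint_log_density(net, {})

    def test_importance_sampling_normalization(self):
        # exp(joint_log_density) must integrate/sum to 1; checked by importance
        # sampling from a heavier-tailed proposal (same graph, inflated
        # variances, CPTs mixed with uniform), which keeps weights stable.
        net = random_cgbn(GeneratorConfig(n_discrete=2, n_continuous=2, edge_prob=0.6, seed=3))
        prop_params = {}
        for name, p in net.params.items():
            if isinstance(p, DiscreteNodeParams):
                cpt = 0.5 * p.cpt + 0.5 / p.cpt.shape[1]
                prop_params[name] = DiscreteNodeParams(p.parents, p.states, cpt)
            else:
                prop_params[name] = CLGNodeParams(
                    p.disc_parents, p.cont_parents, p.intercepts, p.coefs, p.variances * 2.5
                )
        proposal = CGBayesNet(
            net.structure.copy(), net.variables, prop_params, phenotype=net.phenotype
        )
        n = 100_000
        samples = sample_dataset(proposal, n, seed=4)
        kinds = {v.name: v.kind for v in net.variables}
        log_w = np.empty(n)
        for i, rec in enumerate(samples.frame.to_dict("records")):
            assign = {k: (v if kinds[k] == "discrete" else float(v)) for k, v in rec.items()}
            log_w[i] = joint_log_density(net, assign) - joint_log_density(proposal, assign)
        w = np.exp(log_w)
        se = w.std(ddof=1) / np.sqrt(n)
        assert abs(w.mean() - 1.0) < 3 * se


class TestPredict:
    def test_symmetric_gaussian_evidence_gives_half(self, gaussian_naive_net):
        assert predict(gaussian_naive_net, {"X": 0.0}, "phenotype") == pytest.approx([0.5, 0.5])

    def test_gaussian_likelihood_ratio(self, gaussian_naive_net):
        post = predict(gaussian_naive_net, {"X": 1.0}, "phenotype")
        assert post[1] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-5)
        assert post[1] == pytest.approx(0.88080, abs=1e-5)

    def test_cpt_bayes_rule(self, cpt_naive_net):
        post = predict(cpt_naive_net, {"D": "1"}, "phenotype")
        assert post == pytest.approx([9.0 / 11.0, 2.0 / 11.0], abs=1e-12)

    def test_unseen_state_rejected(self, cpt_naive_net):
        with pytest.raises(ValueError, match="unseen"):
            predict(cpt_naive_net, {"D": "3"}, "phenotype")

    def test_target_in_evidence_rejected(self, cpt_naive_net):
        with pytest.raises(ValueError):
            predict(cpt_naive_net, {"phenotype": "a", "D": "1"}, "phenotype")

    def test_enumeration_guard_raises_on_huge_hidden_space(self):
        nodes = [f"d{i}" for i in range(24)]
        vs = tuple(VariableSpec(n, "discrete", ("0", "1")) for n in nodes)
        g = DAGStructure(nodes, [(nodes[i], nodes[i + 1]) for i in range(23)])
        params = {}
        for i, n in enumerate(nodes):
            if i == 0:
                params[n] = DiscreteNodeParams((), ("0", "1"), np.array([[0.5, 0.5]]))
            else:
                params[n] = DiscreteNodeParams(
                    (nodes[i - 1],), ("0", "1"), np.array([[0.7, 0.3], [0.3, 0.7]])
                )
        net = CGBayesNet(g, vs, params)
        with pytest.raises(RuntimeError, match="guard"):
            predict(net, {nodes[-1]: "1"}, nodes[0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_cgbn(
            GeneratorConfig(
                n_discrete=4, n_continuous=4, edge_prob=0.4, seed=seed, balanced_phenotype=False
            )
        )
        data = sample_dataset(net, 5, seed=seed)
        names = list(net.structure.nodes)
        for trial in range(10):
            target = str(rng.choice([n for n in names if net.kind(n) == "discrete"]))
            ev = {}
            for n in names:
                if n != target and rng.random() < 0.6:
                    v = data.frame.iloc[trial % 5][n]
                    ev[n] = v if net.kind(n) == "discrete" else float(v)
            mine = predict(net, ev, target)
            oracle = dense_predict(net, ev, target)
            assert np.abs(mine - oracle).max() < 1e-10
            assert mine.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_forward_sampling_conditional(self):
        net = random_cgbn(
            GeneratorConfig(n_discrete=3, n_continuous=2, edge_prob=0.5, seed=7,
                            balanced_phenotype=False)
        )
        big = sample_dataset(net, 1_000_000, seed=9)
        disc = [n for n in net.structure.nodes if net.kind(n) == "discrete"]
        target, ev_node = disc[0], disc[1]
        ev_state = net.var(ev_node).states[0]
        mask = big.frame[ev_node] == ev_state
        emp = float((big.frame[target][mask] == net.var(target).states[1]).mean())
        exact = predict(net, {ev_node: ev_state}, target)[1]
        se = np.sqrt(emp * (1 - emp) / mask.sum())
        assert abs(emp - exact) < 3 * se


class TestPredictDataset:
    def test_identical_rows_identical_posteriors(self, strong_net):
        data = sample_dataset(strong_net, 1, seed=0)
        rep = data.take([0, 0, 0])
        res = predict_dataset(strong_net, rep)
        assert np.allclose(res.probabilities[0], res.probabilities[1])
        assert np.allclose(res.probabilities[0], res.probabilities[2])

    def test_non_blanket_variable_is_irrelevant(self, strong_net):
        data = sample_dataset(strong_net, 20, seed=1)
        base = predict_dataset(strong_net, data).probabilities
        perturbed = data.frame.copy()
        perturbed["C3"] = perturbed["C3"] + 100.0  # C3 is outside the blanket
        data2 = type(data)(perturbed, data.variables, data.phenotype)
        assert np.allclose(base, predict_dataset(strong_net, data2).probabilities)
        # blanket-restricted posterior equals full-evidence enumeration
        row = data.frame.iloc[0]
        full_ev = {
            v.name: (row[v.name] if v.kind == "discrete" else float(row[v.name]))
            for v in strong_net.variables
            if v.name != "phenotype"
        }
        assert np.allclose(base[0], dense_predict(strong_net, full_ev, "phenotype"))

    def test_mean_posterior_of_true_class_beats_chance(self, strong_net):
        data = sample_dataset(strong_net, 200, seed=2)
        res = predict_dataset(strong_net, data)
        codes = data.codes("phenotype")
        true_probs = res.probabilities[np.arange(data.n), codes]
        assert true_probs.mean() > 0.5

    def test_missing_blanket_column_named_in_error(self, strong_net):
        data = sample_dataset(strong_net, 5, seed=3)
        frame = data.frame.drop(columns=["C1"])
        variables = [v for v in data.variables if v.name != "C1"]
        data2 = type(data)(frame, variables, data.phenotype)
        with pytest.raises(ValueError, match="C1"):
            predict_dataset(strong_net, data2)
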