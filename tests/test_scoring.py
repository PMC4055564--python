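"""Family scores against independent oracles, score properties, BF filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cgbn.model import DAGStructure, MixedDataset, VariableSpec
from cgbn.scoring import (
    PriorHyper,
    bayes_factor_filter,
    bdeu_family_score,
    clg_family_score,
    family_score,
    network_score,
)
from cgbn.simulate import GeneratorConfig, random_cgbn, sample_dataset

from oracles import quadrature_nig_marginal, sequential_bdeu


def _disc_ds(child_codes, parent_codes=None, r=2, rp=2):
    cols = {"y": [str(c) for c in child_codes]}
    specs = [VariableSpec("y", "discrete", tuple(str(i) for i in range(r)))]
    if parent_codes is not None:
        cols["p"] = [str(c) for c in parent_codes]
        specs.append(VariableSpec("p", "discrete", tuple(str(i) for i in range(rp))))
    return MixedDataset(pd.DataFrame(cols), specs, "y")


class TestBDeu:
    def test_single_observation_is_uniform_predictive(self):
        for r in (2, 3):
            ds = _disc_ds([0], r=r)
            s = bdeu_family_score(ds, "y", [], PriorHyper(alpha=0.7))
            assert s.log_marginal_likelihood == pytest.approx(np.log(1.0 / r), abs=1e-12)

    def test_three_obs_alpha_two_closed_form(self):
        ds = _disc_ds([0, 0, 1])
        s = bdeu_family_score(ds, "y", [], PriorHyper(alpha=2.0))
        assert s.log_marginal_likelihood == pytest.approx(np.log(1.0 / 12.0), abs=1e-12)

    def test_stratified_by_binary_parent(self):
        ds = _disc_ds([0, 1, 0, 1], parent_codes=[0, 0, 1, 1])
        s = bdeu_family_score(ds, "y", ["p"], PriorHyper(alpha=4.0))
        assert s.log_marginal_likelihood == pytest.approx(np.log(1.0 / 36.0), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("r,q", [(2, 1), (2, 2), (3, 1), (3, 4), (2, 4)])
    def test_matches_sequential_predictive_oracle(self, alpha, r, q):
        rng = np.random.default_rng(hash((alpha, r, q)) % 2**31)
        for n in (1, 3, 6):
            codes = rng.integers(0, r, n)
            pidx = rng.integers(0, q, n)
            oracle = sequential_bdeu(codes, pidx, r, q, alpha)
            if q == 1:
                ds = _disc_ds(codes, r=r)
                mine = bdeu_family_score(ds, "y", [], PriorHyper(alpha=alpha))
            elif q in (2, 4):
                if q == 2:
                    ds = _disc_ds(codes, parent_codes=pidx, r=r, rp=2)
                    parents = ["p"]
                else:
                    cols = {
                        "y": [str(c) for c in codes],
                        "a": [str(i // 2) for i in pidx],
                        "b": [str(i % 2) for i in pidx],
                    }
                    specs = [
                        VariableSpec("y", "discrete", tuple(str(i) for i in range(r))),
                        VariableSpec("a", "discrete", ("0", "1")),
                        VariableSpec("b", "discrete", ("0", "1")),
                    ]
                    ds = MixedDataset(pd.DataFrame(cols), specs, "y")
                    parents = ["a", "b"]
                mine = bdeu_family_score(ds, "y", parents, PriorHyper(alpha=alpha))
            assert mine.log_marginal_likelihood == pytest.approx(oracle, abs=1e-10)

    def test_exp_score_sums_to_one_over_all_datasets(self):
        # the marginal likelihood is a probability over datasets of fixed size
        for n in (1, 2, 3):
            total = 0.0
            for seq in itertools.product([0, 1], repeat=n):
                ds = _disc_ds(list(seq))
                total += np.exp(
                    bdeu_family_score(ds, "y", [], PriorHyper(alpha=1.5)).log_marginal_likelihood
                )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_type_and_domain_errors(self):
        cols = {"y": ["0", "1"], "x": [0.1, 0.2]}
        specs = [VariableSpec("y", "discrete", ("0", "1")), VariableSpec("x", "continuous")]
        ds = MixedDataset(pd.DataFrame(cols), specs, "y")
        with pytest.raises(TypeError):
            bdeu_family_score(ds, "x", [], PriorHyper())
        with pytest.raises(TypeError):
            bdeu_family_score(ds, "y", ["x"], PriorHyper())
        with pytest.raises(ValueError):
            PriorHyper(alpha=0.0)


def _cont_ds(y, x=None, groups=None):
    cols = {"y": y, "phenotype": groups if groups is not None else ["a"] * len(y)}
    specs = [
        VariableSpec("y", "continuous"),
        VariableSpec("phenotype", "discrete", tuple(sorted(set(cols["phenotype"])))),
    ]
    if x is not None:
        cols["x"] = x
        specs.append(VariableSpec("x", "continuous"))
    return MixedDataset(pd.DataFrame(cols), specs, "phenotype")


class TestCLG:
    @pytest.mark.parametrize("n,with_parent", [(3, False), (6, False), (10, False), (5, True), (8, True)])
    @pytest.mark.parametrize("nu,s0", [(1.0, 1.0), (2.0, 0.5)])
    def test_matches_quadrature_oracle(self, n, with_parent, nu, s0):
        rng = np.random.default_rng(n * 7 + with_parent)
        y = rng.normal(0.5, 1.2, n)
        x = rng.normal(0.0, 1.0, n) if with_parent else None
        ds = _cont_ds(y, x)
        mine = clg_family_score(
            ds, "y", ["x"] if with_parent else [], [], PriorHyper(nu=nu, sigma0_sq=s0)
        ).log_marginal_likelihood
        X = np.column_stack([np.ones(n)] + ([x] if with_parent else []))
        oracle = quadrature_nig_marginal(y, X, nu, s0)
        assert mine == pytest.approx(oracle, rel=1e-4)

    def test_discrete_parent_stratifies_like_split_datasets(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 8)
        g = ["a"] * 4 + ["b"] * 4
        ds = _cont_ds(list(y), groups=g)
        whole = clg_family_score(ds, "y", [], ["phenotype"], PriorHyper()).log_marginal_likelihood
        part = sum(
            clg_family_score(_cont_ds(list(y[i : i + 4])), "y", [], [], PriorHyper()).log_marginal_likelihood
            for i in (0, 4)
        )
        assert whole == pytest.approx(part, abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 12)
        x = rng.normal(0, 1, 12)
        ds = _cont_ds(y, x)
        perm = rng.permutation(12)
        ds2 = _cont_ds(y[perm], x[perm])
        a = clg_family_score(ds, "y", ["x"], [], PriorHyper()).log_marginal_likelihood
        b = clg_family_score(ds2, "y", ["x"], [], PriorHyper()).log_marginal_likelihood
        assert a == pytest.approx(b, abs=1e-10)

    def test_true_regression_parent_improves_score(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 50)
        y = 2.0 * x + rng.normal(0, 0.1, 50)
        ds = _cont_ds(y, x)
        with_parent = clg_family_score(ds, "y", ["x"], [], PriorHyper()).log_marginal_likelihood
        without = clg_family_score(ds, "y", [], [], PriorHyper()).log_marginal_likelihood
        assert with_parent > without

    def test_discrete_child_rejected(self):
        ds = _disc_ds([0, 1])
        with pytest.raises(TypeError):
            clg_family_score(ds, "y", [], [], PriorHyper())


class TestNetworkScore:
    def test_empty_structure_is_sum_of_parentless_families(self):
        net = random_cgbn(GeneratorConfig(n_discrete=3, n_continuous=3, edge_prob=0.5, seed=1))
        data = sample_dataset(net, 30, seed=2)
        empty = DAGStructure(data.names)
        prior = PriorHyper()
        expected = sum(family_score(data, v, set(), prior) for v in data.names)
        assert network_score(empty, data, prior) == pytest.approx(expected, abs=1e-10)

    def test_decomposability_under_parent_swap(self):
        net = random_cgbn(GeneratorConfig(n_discrete=3, n_continuous=3, edge_prob=0.5, seed=4))
        data = sample_dataset(net, 40, seed=5)
        prior = PriorHyper()
        g = DAGStructure(data.names)
        child = data.continuous_names[0]
        parent = data.discrete_names[0]
        base = network_score(g, data, prior)
        g.add_edge(parent, child)
        delta_total = network_score(g, data, prior) - base
        delta_family = family_score(data, child, {parent}, prior) - family_score(
            data, child, set(), prior
        )
        assert delta_total == pytest.approx(delta_family, abs=1e-10)

    def test_spurious_edge_usually_decreases_score(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cols = {"x": rng.normal(0, 1, 500), "z": rng.normal(0, 1, 500),
                    "phenotype": list(rng.choice(["a", "b"], 500))}
            specs = [VariableSpec("x", "continuous"), VariableSpec("z", "continuous"),
                     VariableSpec("phenotype", "discrete", ("a", "b"))]
            data = MixedDataset(pd.DataFrame(cols), specs, "phenotype")
            prior = PriorHyper()
            empty = DAGStructure(data.names)
            with_edge = DAGStructure(data.names, [("x", "z")])
            if network_score(with_edge, data, prior) < network_score(empty, data, prior):
                wins += 1
        assert wins >= 9

    def test_true_structure_beats_empty_on_strong_signal(self):
        from conftest import strong_five_node_net

        net = strong_five_node_net()
        data = sample_dataset(net, 1000, seed=7)
        prior = PriorHyper()
        assert network_score(net.structure, data, prior) >= network_score(
            DAGStructure(data.names), data, prior
        )

    def test_cg_violation_rejected(self):
        net = random_cgbn(GeneratorConfig(n_discrete=2, n_continuous=2, edge_prob=0.0, seed=0))
        data = sample_dataset(net, 10, seed=0)
        g = DAGStructure(data.names, [(data.continuous_names[0], data.discrete_names[0])])
        with pytest.raises(ValueError):
            network_score(g, data, PriorHyper())


class TestBayesFactorFilter:
    def test_copy_of_phenotype_ranks_first_noise_filtered(self):
        rng = np.random.default_rng(0)
        ph = list(rng.choice(["a", "b"], 100))
        cols = {"phenotype": ph, "copy": ph, "noise1": rng.normal(0, 1, 100),
                "noise2": list(rng.choice(["x", "y"], 100))}
        specs = [
            VariableSpec("phenotype", "discrete", ("a", "b")),
            VariableSpec("copy", "discrete", ("a", "b")),
            VariableSpec("noise1", "continuous"),
            VariableSpec("noise2", "discrete", ("x", "y")),
        ]
        data = MixedDataset(pd.DataFrame(cols), specs, "phenotype")
        out = bayes_factor_filter(data, "phenotype", ["copy", "noise1", "noise2"], 0.0)
        assert out and out[0][0] == "copy" and out[0][1] > 0

    def test_null_candidate_filtered_at_zero_threshold(self):
        rng = np.random.default_rng(1)
        cols = {"phenotype": list(rng.choice(["a", "b"], 1000)), "v": rng.normal(0, 1, 1000)}
        specs = [VariableSpec("phenotype", "discrete", ("a", "b")), VariableSpec("v", "continuous")]
        data = MixedDataset(pd.DataFrame(cols), specs, "phenotype")
        assert bayes_factor_filter(data, "phenotype", ["v"], 0.0) == []

    def test_empty_candidates_and_usage_error(self):
        ds = _disc_ds([0, 1])
        assert bayes_factor_filter(ds, "y", [], 0.0) == []
        with pytest.raises(ValueError):
            bayes_factor_filter(ds, "y", ["y"], 0.0)
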