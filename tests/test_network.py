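"""CPT estimation, Markov boundaries, exact inference and interventions."""

import numpy as np
import pytest

import camnet as cm
from camnet.network import ZeroSupportError, fit_parameters
from camnet.synthetic import generic_schema, network_cohort

from conftest import strong_random_net, toy_collider_net


def _brute_posterior(net, target, evidence):
    jt = net.joint_table()
    idx = [slice(None)] * len(jt.vars)
    for k, v in evidence.items():
        idx[jt.vars.index(k)] = v
    sub = jt.table[tuple(idx)]
    remaining = [v for v in jt.vars if v not in evidence]
    t_ax = remaining.index(target)
    other = tuple(i for i in range(len(remaining)) if i != t_ax)
    m = sub.sum(axis=other) if other else sub
    return m / m.sum()


class TestFitParameters:
    def test_dirichlet_posterior_mean_closed_form(self):
        schema = generic_schema({"x": 2, "o": 2}, "o")
        x = np.array([1] * 30 + [0] * 70)
        cohort = cm.CohortTable(schema, np.column_stack([x, np.zeros(100, int)]))
        net = fit_parameters(cm.PDAG(["x", "o"]), cohort, prior_strength=1.0)
        assert net.cpts["x"][1] == pytest.approx(30.5 / 101, rel=1e-12)

    def test_prior_to_zero_recovers_mle(self):
        schema = generic_schema({"x": 2, "o": 2}, "o")
        x = np.array([1] * 30 + [0] * 70)
        cohort = cm.CohortTable(schema, np.column_stack([x, np.zeros(100, int)]))
        net = fit_parameters(cm.PDAG(["x", "o"]), cohort, prior_strength=0.0)
        assert net.cpts["x"][1] == pytest.approx(0.3, rel=1e-12)

    def test_unobserved_parent_configuration_is_uniform(self):
        schema = generic_schema({"p": 2, "c": 2, "o": 2}, "o")
        vals = np.zeros((50, 3), dtype=int)  # p always 0
        cohort = cm.CohortTable(schema, vals)
        dag = cm.PDAG(["p", "c", "o"], directed=[("p", "c")])
        net = fit_parameters(dag, cohort, prior_strength=1.0)
        assert net.cpts["c"][1] == pytest.approx([0.5, 0.5])

    def test_parameter_recovery_at_large_n(self):
        truth, schema = cm.six_node_truth(3)
        cohort = cm.generate_cohort(cm.GeneratorConfig(truth, schema, 50000, 11))
        net = fit_parameters(truth.to_pdag(), cohort, prior_strength=1.0)
        err = max(
            np.abs(net.cpts[v] - truth.aligned_cpt(v)).max() for v in truth.nodes
        )
        assert err < 0.02

    def test_cyclic_structure_rejected(self):
        with pytest.raises(cm.GraphError):
            cm.CausalNetwork(
                {"a": ("b",), "b": ("a",)}, {"a": 2, "b": 2},
                {"a": np.eye(2), "b": np.eye(2)},
            )


class TestMarkovBoundary:
    def test_chain_and_collider(self):
        chain = cm.PDAG(["A", "B", "C"], directed=[("A", "B"), ("B", "C")])
        schema = generic_schema({"A": 2, "B": 2, "C": 2}, "C")
        cohort = cm.CohortTable(schema, np.zeros((4, 3), int))
        net = fit_parameters(chain, cohort)
        assert net.markov_boundary("B") == {"A", "C"}
        coll = toy_collider_net()
        assert coll.markov_boundary("A") == {"B", "C"}

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            toy_collider_net().markov_boundary("nope")


class TestInference:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_joint_enumeration(self, seed):
        net = strong_random_net(6, seed, card=2)
        rng = np.random.default_rng(seed + 100)
        for _ in range(8):
            k = int(rng.integers(0, 5))
            obs = list(rng.choice(net.nodes, size=k, replace=False))
            target = next(v for v in net.nodes if v not in obs)
            ev = {v: int(rng.integers(0, net.cards[v])) for v in obs}
            got = net.infer(target, ev)
            want = _brute_posterior(net, target, ev)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_three_node_toy_partial_evidence(self):
        net = toy_collider_net()
        got = net.infer("A", {"C": 1})
        want = _brute_posterior(net, "A", {"C": 1})
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_markov_boundary_sufficiency(self):
        truth, schema = cm.six_node_truth(7)
        cohort = cm.generate_cohort(cm.GeneratorConfig(truth, schema, 3000, 8))
        net = fit_parameters(truth.to_pdag(), cohort)
        mb = sorted(net.markov_boundary("AMI"))
        others = [v for v in net.nodes if v != "AMI"]
        for i in range(0, cohort.n, 100):
            full = {v: int(cohort.column(v)[i]) for v in others}
            part = {v: full[v] for v in mb}
            p_full = net.infer("AMI", full)[1]
            p_part = net.infer("AMI", part)[1]
            assert abs(p_full - p_part) < 1e-12

    def test_conditioning_on_target_rejected(self):
        net = toy_collider_net()
        with pytest.raises(ValueError):
            net.infer("C", {"C": 1})

    def test_zero_support_flagged(self):
        # deterministic CPTs with MLE fitting can give impossible evidence
        net = cm.CausalNetwork(
            {"x": (), "y": ("x",)}, {"x": 2, "y": 2},
            {"x": np.array([1.0, 0.0]), "y": np.eye(2)},
        )
        with pytest.raises(ZeroSupportError):
            net.infer("y", {"x": 1})


class TestIntervention:
    def test_do_on_root_equals_conditioning(self):
        net = toy_collider_net()
        np.testing.assert_allclose(
            cm.intervention_distribution(net, "A", 1, "C"),
            net.infer("C", {"A": 1}),
            atol=1e-12,
        )

    def test_do_severs_back_inference(self):
        net = toy_collider_net()
        np.testing.assert_allclose(
            cm.intervention_distribution(net, "C", 1, "A"),
            net.infer("A"),
            atol=1e-12,
        )

    def test_clamping_target_rejected(self):
        with pytest.raises(ValueError):
            cm.intervention_distribution(toy_collider_net(), "C", 0, "C")


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        net = strong_random_net(4, 2)
        p = tmp_path / "model.json"
        net.to_json(p)
        back = cm.CausalNetwork.from_json(p)
        assert back.parents == net.parents
        for v in net.nodes:
            np.testing.assert_allclose(back.cpts[v], net.cpts[v])

    def test_sampling_deterministic(self):
        net = strong_random_net(4, 3)
        a = net.sample(100, np.random.default_rng(5))
        b = net.sample(100, np.random.default_rng(5))
        for v in net.nodes:
            assert (a[v] == b[v]).all()


class TestClassifier:
    def test_sklearn_api_and_missing_evidence(self):
        from sklearn.base import clone

        truth, schema = cm.six_node_truth(1)
        cohort = cm.generate_cohort(cm.GeneratorConfig(truth, schema, 3000, 2))
        df = cohort.to_dataframe().astype(int)
        X = df.drop(columns=["AMI"])
        y = df["AMI"].to_numpy()
        clf = cm.CausalNetworkClassifier(dag=truth.to_pdag(), schema=schema)
        clone(clf)  # get_params/set_params round-trip
        clf.fit(X, y)
        assert clf.markov_boundary_ == truth.markov_boundary("AMI")
        p_full = clf.predict_proba(X.iloc[:50])[:, 1]
        X_mb = X.iloc[:50].copy().astype(float)
        for c in X.columns:
            if c not in clf.markov_boundary_:
                X_mb[c] = np.nan
        p_mb = clf.predict_proba(X_mb)[:, 1]
        np.testing.assert_allclose(p_full, p_mb, atol=1e-12)
        acc = (clf.predict(X) == y).mean()
        assert acc > 0.6

    def test_structure_learning_inside_fit(self):
        truth, schema = cm.six_node_truth(4)
        cohort = cm.generate_cohort(cm.GeneratorConfig(truth, schema, 6000, 3))
        df = cohort.to_dataframe().astype(int)
        clf = cm.CausalNetworkClassifier(schema=schema)
        clf.fit(df.drop(columns=["AMI"]), df["AMI"].to_numpy())
        assert hasattr(clf, "network_")
        assert clf.predict_proba(df.drop(columns=["AMI"]).iloc[:5]).shape == (5, 2)
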