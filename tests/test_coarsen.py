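"""Macro-variable coarse-graining and cohort recoding."""

import numpy as np
import pytest

import camnet as cm
from camnet.coarsen import MacroVariable
from camnet.synthetic import generic_schema, make_cpt, network_cohort


class TestCoarseGrain:
    def test_two_node_instance_rebuilds_outside_edge(self):
        # Z -> X with X—Y unresolved: macro over {X, Y} (4 states for binary
        # members), the Z edge re-attached to the macro node
        g = cm.PDAG(["X", "Y", "Z"], directed=[("Z", "X")], undirected=[("X", "Y")])
        g2, macros = cm.coarse_grain(g, [("X", "Y")], {"X": 2, "Y": 2, "Z": 2})
        assert len(macros) == 1
        m = macros[0]
        assert sorted(m.members) == ["X", "Y"]
        assert m.n_states == 4
        assert g2.directed == {("Z", m.name)}
        assert not g2.undirected

    def test_lifestyle_instance_inherits_all_edges(self):
        g = cm.PDAG(
            ["sex", "smoking", "alcohol", "DYS", "STSA"],
            directed=[("sex", "smoking"), ("sex", "alcohol"),
                      ("smoking", "DYS"), ("smoking", "STSA")],
            undirected=[("smoking", "alcohol")],
        )
        cards = {v: 2 for v in g.nodes}
        g2, macros = cm.coarse_grain(g, [("smoking", "alcohol")], cards)
        m = macros[0]
        assert sorted(m.members) == ["alcohol", "smoking"]
        assert m.n_states == 4
        assert g2.directed == {
            ("sex", m.name), (m.name, "DYS"), (m.name, "STSA")
        }

    def test_empty_unresolved_is_identity(self):
        g = cm.PDAG(["A", "B"], directed=[("A", "B")])
        g2, macros = cm.coarse_grain(g, [], {"A": 2, "B": 2})
        assert g2 == g and macros == []

    def test_overlapping_unresolved_edges_merge(self):
        g = cm.PDAG(["A", "B", "C"], undirected=[("A", "B"), ("B", "C")])
        g2, macros = cm.coarse_grain(
            g, [("A", "B"), ("B", "C")], {"A": 2, "B": 2, "C": 3}
        )
        assert len(macros) == 1
        assert sorted(macros[0].members) == ["A", "B", "C"]
        assert macros[0].n_states == 12
        assert g2.n_edges == 0

    def test_unknown_unresolved_edge_rejected(self):
        g = cm.PDAG(["A", "B"], directed=[("A", "B")])
        with pytest.raises(ValueError):
            cm.coarse_grain(g, [("A", "B")], {"A": 2, "B": 2})

    def test_result_admits_dag_extension(self):
        g = cm.PDAG(
            ["A", "B", "C", "D"],
            directed=[("A", "C"), ("B", "D")],
            undirected=[("C", "D")],
        )
        g2, macros = cm.coarse_grain(g, [("C", "D")], {v: 2 for v in g.nodes})
        assert not g2.undirected or g2.consistent_extension().is_dag()
        assert not g2.has_directed_cycle()


class TestMacroStates:
    def test_encode_decode_bijection(self):
        m = MacroVariable("A+B", ["A", "B"], [2, 3])
        seen = set()
        for a in range(2):
            for b in range(3):
                s = m.encode((a, b))
                assert m.decode(s) == (a, b)
                seen.add(s)
        assert seen == set(range(6))

    def test_smoking_alcohol_combination_labels(self):
        m = MacroVariable("alcohol+smoking", ["alcohol", "smoking"], [2, 2])
        s = m.encode((0, 1))  # does not drink, does smoke
        assert m.state_labels()[s] == "alcohol=0&smoking=1"


class TestRecode:
    def _cohort(self):
        schema = generic_schema({"A": 2, "B": 2, "Z": 2, "O": 2}, "O")
        vals = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 1, 0]])
        miss = np.zeros((3, 4), bool)
        miss[2, 1] = True  # B missing in row 2
        return cm.CohortTable(schema, vals, miss)

    def test_member_columns_replaced(self):
        cohort = self._cohort()
        m = MacroVariable("A+B", ["A", "B"], [2, 2])
        out = cm.recode_cohort(cohort, [m])
        assert out.columns == ["A+B", "Z", "O"]
        assert out.n == 3
        assert out.column("A+B")[0] == m.encode((1, 0))
        assert out.column("A+B")[1] == m.encode((0, 1))

    def test_missing_member_propagates(self):
        out = cm.recode_cohort(
            self._cohort(), [MacroVariable("A+B", ["A", "B"], [2, 2])]
        )
        assert out.column_missing("A+B")[2]
        assert not out.column_missing("A+B")[:2].any()

    def test_no_macros_is_identity(self):
        cohort = self._cohort()
        assert cm.recode_cohort(cohort, []) is cohort

    def test_absent_member_rejected(self):
        with pytest.raises(ValueError):
            cm.recode_cohort(
                self._cohort(), [MacroVariable("A+Q", ["A", "Q"], [2, 2])]
            )


class TestJointPreservation:
    def test_macro_model_reproduces_member_joint(self):
        # truth: sex -> smoking, smoking -> alcohol (direction assumed
        # unidentifiable), smoking -> DYS; coarse-graining smoking+alcohol
        # must preserve the joint over the original variables
        parents = {
            "sex": (), "smoking": ("sex",), "alcohol": ("smoking",),
            "DYS": ("smoking",),
        }
        cpts = {
            "sex": np.array([0.45, 0.55]),
            "smoking": make_cpt(2, (2,), [0.8, 0.2], [[0.0, 1.5]]),
            "alcohol": make_cpt(2, (2,), [0.9, 0.1], [[0.0, 1.8]]),
            "DYS": make_cpt(2, (2,), [0.6, 0.4], [[0.0, 1.2]]),
        }
        truth = cm.CausalNetwork(parents, {k: 2 for k in parents}, cpts)
        cohort = network_cohort(truth, 50000, 31, outcome="DYS")
        g = cm.PDAG(
            ["sex", "smoking", "alcohol", "DYS"],
            directed=[("sex", "smoking"), ("smoking", "DYS")],
            undirected=[("smoking", "alcohol")],
        )
        g2, macros = cm.coarse_grain(
            g, [("smoking", "alcohol")], {k: 2 for k in parents}
        )
        recoded = cm.recode_cohort(cohort, macros)
        dag = g2 if not g2.undirected else g2.consistent_extension()
        net = cm.fit_parameters(dag, recoded, prior_strength=1.0)
        m = macros[0]
        # expand macro states back to (smoking, alcohol) and compare the
        # implied joint with the empirical joint of the original cohort
        jt = net.joint_table()
        order = [jt.vars.index(v) for v in recoded.columns]
        table = np.transpose(jt.table, axes=order)
        counts = np.zeros([2, 2, 2, 2])
        np.add.at(
            counts,
            tuple(cohort.column(v) for v in ["sex", "smoking", "alcohol", "DYS"]),
            1.0,
        )
        emp = counts / counts.sum()
        for sx in range(2):
            for sm in range(2):
                for al in range(2):
                    for dy in range(2):
                        macro_state = m.encode(
                            (al, sm) if m.members == ["alcohol", "smoking"] else (sm, al)
                        )
                        idx = [0] * 3
                        idx[recoded.columns.index("sex")] = sx
                        idx[recoded.columns.index(m.name)] = macro_state
                        idx[recoded.columns.index("DYS")] = dy
                        assert table[tuple(idx)] == pytest.approx(
                            emp[sx, sm, al, dy], abs=0.01
                        )
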