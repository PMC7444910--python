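"""SCC condensation, homeostasis verdicts, classification, effective rates."""

import networkx as nx
import numpy as np
import pytest

import clonesim as cs
from clonesim.network import build_network, scc_condense


def _network(model):
    return build_network(cs.build_mean_field(model))


class TestSCC:
    def test_three_cycle_is_one_scc(self):
        model = cs.CellFateModel.build(
            ["X1", "X2", "X3"],
            transitions=[("X1", "X2", 1.0), ("X2", "X3", 1.0), ("X3", "X1", 1.0)],
        )
        sccs, cond = scc_condense(_network(model))
        assert sccs == [(0, 1, 2)]
        assert cond.number_of_nodes() == 1

    def test_chain_gives_singletons_on_a_path(self):
        model = cs.CellFateModel.build(
            ["X1", "X2", "X3"],
            transitions=[("X1", "X2", 1.0), ("X2", "X3", 1.0)],
            losses={"X3": 1.0},
        )
        sccs, cond = scc_condense(_network(model))
        assert sccs == [(0,), (1,), (2,)]
        assert nx.is_directed_acyclic_graph(cond)
        assert sorted(cond.edges()) == [(0, 1), (1, 2)]

    def test_dh_states_form_single_apex_scc(self):
        dh = cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0)
        sccs, _ = scc_condense(_network(dh))
        assert sccs == [(0, 1)]

    def test_edges_match_positive_kappa(self):
        model, _ = cs.random_homeostatic(cs.GeneratorConfig(seed=9, class_target="GPA"))
        mf = cs.build_mean_field(model)
        net = build_network(mf)
        expected = {
            (i, j)
            for i in range(model.n_states)
            for j in range(model.n_states)
            if i != j and mf.total_transition_rate[i, j] > 0
        }
        assert set(net.graph.edges()) == expected


class TestDominantEigenvalue:
    def test_scalar_block(self):
        assert cs.dominant_eigenvalue(np.array([[0.5 - 2.0]])) == pytest.approx(-1.5)

    def test_balanced_dh_apex_is_critical(self):
        dh = cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0)
        mf = cs.build_mean_field(dh)
        assert cs.dominant_eigenvalue(mf.A) == pytest.approx(0.0, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cs.dominant_eigenvalue(np.zeros((2, 3)))


class TestHomeostasisVerdict:
    def test_balanced_dh_homeostatic(self):
        d = cs.decompose(cs.canonical("DH", lam=1.0, omega_S=0.5, omega_D=1.0, gamma=0.5))
        assert d.verdict == "homeostatic"

    def test_supercritical_committed_compartment(self):
        # committed division rate above its loss rate: mu downstream > 0
        model = cs.CellFateModel.build(
            ["X1", "X2"],
            divisions={
                "X1": (1.0, [(("X1", "X2"), 1.0)]),
                "X2": (2.0, [(("X2", "X2"), 1.0)]),
            },
            losses={"X2": 1.0},
        )
        d = cs.decompose(model)
        assert d.verdict == "supercritical"
        assert d.model_class is None

    def test_supercritical_apex(self):
        # symmetric renewal outweighing symmetric commitment at the apex
        model = cs.CellFateModel.build(
            ["S", "D"],
            divisions={
                "S": (1.0, [(("S", "S"), 0.35), (("S", "D"), 0.5), (("D", "D"), 0.15)])
            },
            losses={"D": 1.0},
        )
        d = cs.decompose(model)
        assert d.verdict == "supercritical"

    def test_subcritical_apex(self):
        model = cs.CellFateModel.build(
            ["S", "D"],
            divisions={
                "S": (1.0, [(("S", "S"), 0.15), (("S", "D"), 0.5), (("D", "D"), 0.35)])
            },
            losses={"D": 1.0},
        )
        assert cs.decompose(model).verdict == "subcritical"

    def test_two_independent_lineages_rejected(self):
        model = cs.CellFateModel.build(
            ["X1", "X2"],
            divisions={
                "X1": (1.0, [(("X1", "X1"), 1.0)]),
                "X2": (1.0, [(("X2", "X2"), 1.0)]),
            },
            losses={"X1": 1.0, "X2": 1.0},
        )
        assert cs.decompose(model).verdict == "multiple_apexes"

    def test_condensation_order_apex_dominates(self):
        for seed in range(4):
            model, d = cs.random_homeostatic(cs.GeneratorConfig(seed=seed, class_target="GPA"))
            apex_mu = max(d.mu)
            assert apex_mu == pytest.approx(0.0, abs=1e-8)
            assert all(mu <= apex_mu + 1e-12 for mu in d.mu)


class TestClassification:
    def test_canonical_classes(self):
        assert cs.decompose(cs.canonical("IA", lam=1.0, gamma=1.0)).model_class == "GIA"
        assert cs.decompose(cs.canonical("PA", lam=1.0, r=0.25, gamma=1.0)).model_class == "GPA"
        assert (
            cs.decompose(cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0)).model_class
            == "GPA"
        )
        assert cs.decompose(cs.canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0)).model_class == "GIA"

    def test_r_loss_makes_model_gpa(self):
        # an apex state with direct loss breaks the conservation law
        model = cs.CellFateModel.build(
            ["S", "D"],
            divisions={"S": (1.0, [(("S", "S"), 0.5), (("D", "D"), 0.5)])},
            losses={"D": 2.0},
        )
        d = cs.decompose(model)
        assert d.verdict == "homeostatic" and d.model_class == "GPA"


class TestStationaryAndEffectiveRates:
    def test_gia0_stationary_closed_form(self):
        d = cs.decompose(cs.canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0))
        assert d.stationary == pytest.approx([1.0, 2.0], abs=1e-9)
        d2 = cs.decompose(cs.canonical("GIA0", lam1=1.0, lam2=1.0, gamma=2.0))
        assert d2.stationary[1] == pytest.approx(1.0, abs=1e-9)

    def test_balanced_dh_stationary_uniform(self):
        d = cs.decompose(cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0))
        assert d.stationary == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_gia0_effective_rates_identity(self):
        d = cs.decompose(cs.canonical("GIA0", lam1=1.5, lam2=0.5, gamma=2.0))
        eff = d.effective
        assert eff.lambda_R == pytest.approx(1.5)
        assert eff.omega_RC == 0.0
        assert eff.gamma_C == pytest.approx(2.0)
        assert eff.lambda_hat_R == pytest.approx(0.75)

    def test_gpa2_effective_rates_identity(self):
        d = cs.decompose(
            cs.canonical("GPA2", lam1=1.0, r1=0.3, r2=0.1, omega=0.2, lam2=0.5, gamma=1.0)
        )
        eff = d.effective
        assert eff.lambda_R == pytest.approx(1.0)
        assert eff.r_RR == pytest.approx(0.3)
        assert eff.r_CC == pytest.approx(0.1)
        assert eff.omega_RC == pytest.approx(0.2)
        assert eff.lambda_C == pytest.approx(0.5)
        assert eff.gamma_C == pytest.approx(1.0)

    def test_dh_has_no_committed_compartment(self):
        d = cs.decompose(cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0))
        assert d.C_states == ()
        assert d.effective.gamma_C is None
        assert "no committed compartment" in d.effective.note

    @pytest.mark.parametrize("seed", range(6))
    def test_gpa_balance_identity(self, seed):
        """Stationarity forces lam_R*r_RR = lam_R*r_CC + omega_RC + gamma_R."""
        model, d = cs.random_homeostatic(cs.GeneratorConfig(seed=seed, class_target="GPA"))
        eff = d.effective
        lhs = eff.lambda_R * eff.r_RR
        rhs = eff.lambda_R * eff.r_CC + eff.omega_RC + eff.gamma_R
        assert lhs == pytest.approx(rhs, rel=1e-6)
        assert eff.gamma_C > eff.lambda_C

    def test_report_is_json_serialisable(self):
        import json

        d = cs.decompose(cs.canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0))
        text = json.dumps(d.report())
        assert '"model_class": "GIA"' in text
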