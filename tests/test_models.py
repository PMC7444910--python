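"""Model definition, validation and mean-field construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonesim as cs
from clonesim.models import model_from_dict, model_to_dict

from conftest import random_small_model


class TestValidation:
    def test_well_formed_canonical_models_pass(self):
        for model in (
            cs.canonical("IA", lam=1.0, gamma=1.0),
            cs.canonical("PA", lam=1.0, r=0.25, gamma=1.0),
            cs.canonical("DH", lam=1.0, omega_S=1.0, omega_D=1.0, gamma=1.0),
            cs.canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0),
        ):
            assert cs.validate_model(model) == []

    def test_unnormalised_daughter_probabilities_reported(self):
        bad = cs.CellFateModel.build(
            ["X1"], divisions={"X1": (1.0, [(("X1", "X1"), 0.6)])}
        )
        report = cs.validate_model(bad)
        assert len(report) == 1 and "sum" in report[0] and "X1" in report[0]

    def test_negative_transition_rate_reported(self):
        bad = cs.CellFateModel.build(
            ["X1", "X2"], transitions=[("X1", "X2", -1.0)], losses={"X2": 1.0}
        )
        assert any("negative rate" in line for line in cs.validate_model(bad))

    def test_daughter_pairs_without_division_rate_reported(self):
        bad = cs.CellFateModel.build(
            ["X1"], divisions={"X1": (0.0, [(("X1", "X1"), 1.0)])}
        )
        assert any("lambda = 0" in line for line in cs.validate_model(bad))


class TestPerDaughterProbability:
    def test_asymmetric_division_splits_evenly(self, gia0_model):
        assert cs.per_daughter_probability(gia0_model, "X1", "X1") == 0.5
        assert cs.per_daughter_probability(gia0_model, "X1", "X2") == 0.5

    def test_pa_self_renewal_probability(self, pa_model):
        # r*1 (S+S) + (1-2r)*1/2 (S+D) = 1/2 regardless of r
        assert cs.per_daughter_probability(pa_model, "S", "S") == pytest.approx(0.5)

    def test_pure_duplication(self, gia0_model):
        assert cs.per_daughter_probability(gia0_model, "X2", "X2") == 1.0

    def test_non_dividing_state_raises(self):
        ia = cs.canonical("IA", lam=1.0, gamma=1.0)
        with pytest.raises(ValueError, match="does not divide"):
            cs.per_daughter_probability(ia, "D", "D")


class TestMeanField:
    def test_two_state_gia_matrix(self):
        lam1, lam2, gamma = 0.7, 0.3, 1.1
        mf = cs.build_mean_field(cs.canonical("GIA0", lam1=lam1, lam2=lam2, gamma=gamma))
        assert np.allclose(mf.A, [[0.0, 0.0], [lam1, lam2 - gamma]])

    def test_ia_matrix(self):
        lam, gamma = 1.3, 0.4
        mf = cs.build_mean_field(cs.canonical("IA", lam=lam, gamma=gamma))
        assert np.allclose(mf.A, [[0.0, 0.0], [lam, -gamma]])

    def test_mean_trajectory_solves_ode(self, gia0_model):
        mf = cs.build_mean_field(gia0_model)
        traj = mf.mean_trajectory([1.0, 0.0], [0.0, 40.0])
        assert np.allclose(traj[0], [1.0, 0.0])
        # stationary committed mean lambda1/(gamma - lambda2) = 2
        assert traj[1] == pytest.approx([1.0, 2.0], abs=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_column_sums_and_cooperativity(self, seed):
        """Algebraic identities of A: column i sums to lambda_i - gamma_i and
        off-diagonal entries are never negative, for any valid model."""
        model = random_small_model(np.random.default_rng(seed))
        mf = cs.build_mean_field(model)
        expected = model.division_rate - model.loss_rate
        assert np.allclose(mf.A.sum(axis=0), expected, atol=1e-12)
        off = mf.A - np.diag(np.diag(mf.A))
        assert (off >= 0).all()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_per_daughter_probabilities_normalised(self, seed):
        model = random_small_model(np.random.default_rng(seed))
        for i, s in enumerate(model.states):
            if model.division_rate[i] > 0:
                total = sum(
                    cs.per_daughter_probability(model, s, t) for t in model.states
                )
                assert total == pytest.approx(1.0, abs=1e-12)


class TestMinProcessRate:
    def test_min_of_positive_rates(self):
        model = cs.canonical("GIA0", lam1=0.5, lam2=0.0, gamma=3.0)
        assert cs.min_process_rate(model) == 0.5

    def test_zero_rates_excluded(self):
        dh_like = cs.CellFateModel.build(
            ["S", "D"],
            divisions={"S": (1.0, [(("S", "D"), 1.0)])},
            transitions=[("S", "D", 0.0)],
            losses={"D": 1.0},
        )
        assert cs.min_process_rate(dh_like) == 1.0

    def test_all_zero_model_raises(self):
        frozen = cs.CellFateModel.build(["X1", "X2"])
        with pytest.raises(ValueError, match="no active process"):
            cs.min_process_rate(frozen)


class TestSchema:
    @pytest.mark.parametrize(
        "model",
        [
            cs.canonical("PA", lam=1.0, r=0.25, gamma=1.0),
            cs.canonical("DH", lam=1.0, omega_S=2.0, omega_D=1.0, gamma=2.0),
            cs.canonical("GIAB", lam_a=1.0, lam_b=3.0, omega_ab=0.1, omega_ba=0.1, gamma=1.0),
        ],
        ids=["PA", "DH", "GIAB"],
    )
    def test_dict_round_trip_is_exact(self, model):
        assert model_from_dict(model_to_dict(model)) == model

    def test_file_round_trip_is_exact(self, tmp_path):
        model, _ = cs.random_homeostatic(cs.GeneratorConfig(seed=5, class_target="GPA"))
        path = tmp_path / "model.yaml"
        cs.save_model(model, path)
        assert cs.load_model(path) == model
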