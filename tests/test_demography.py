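import numpy as np
import pytest

from eusocia.config import ModelConfig, TraitState
from eusocia.demography import (
    HELPER,
    SOLITARY_DAUGHTER,
    SPERM_SPRING,
    SPERM_SUMMER,
    SPRING_MALE,
    SURVIVOR,
    build_transition_matrices,
    dominant_right_eigenpair,
    generation_overlap,
    helper_effect,
    stable_class_distribution,
)
from conftest import random_config, random_traits
from oracles import cohort_head_counts, iterate_to_stationarity


class TestTransitionMatrices:
    def test_no_helpers_without_helping(self, fh_haplo):
        M1, _ = build_transition_matrices(fh_haplo, TraitState(0.5, 0.5, 0.0))
        assert M1[HELPER - 2, 0] == 0.0

    def test_all_male_spring_brood_empties_daughter_classes(self, fh_haplo):
        M1, _ = build_transition_matrices(fh_haplo, TraitState(1.0, 0.5, 0.3))
        assert M1[SOLITARY_DAUGHTER - 2, 0] == 0.0
        assert M1[HELPER - 2, 0] == 0.0

    def test_helper_inflow_arithmetic(self, fh_haplo):
        # F1=2, z1=0.5, h=0.5: helper inflow per foundress = 2*0.5*0.5
        M1, _ = build_transition_matrices(fh_haplo, TraitState(0.5, 0.5, 0.5))
        assert M1[HELPER - 2, 0] == pytest.approx(0.5)

    def test_sperm_column_contains_only_zeroes(self, fh_haplo, even_traits):
        M1, _ = build_transition_matrices(fh_haplo, even_traits)
        assert np.all(M1[:, 1] == 0.0)


class TestStableDistribution:
    def test_matches_brute_force_iteration(self, fh_haplo, even_traits):
        state = stable_class_distribution(fh_haplo, even_traits)
        oracle = iterate_to_stationarity(state.D, n_iter=10_000)
        assert np.allclose(state.u / state.u.sum(), oracle, atol=1e-10)

    @pytest.mark.parametrize("life_cycle", ["FH", "LD"])
    def test_eigenvalue_one_and_closed_form_across_random_configs(self, life_cycle):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cfg = random_config(rng, life_cycle)
            traits = random_traits(rng)
            # check=True verifies lambda(D)=1 to 1e-10 and closed-form u
            # against the dominant eigenvector to 1e-8
            state = stable_class_distribution(cfg, traits, check=True)
            lam, _ = dominant_right_eigenpair(state.D)
            assert lam == pytest.approx(1.0, abs=1e-10)

    def test_no_surviving_foundresses_when_Sf_zero(self, even_traits):
        cfg = ModelConfig(S_f=0.0)
        state = stable_class_distribution(cfg, even_traits)
        assert state.u[SURVIVOR] == 0.0
        assert state.u[SPERM_SUMMER] == 0.0

    def test_no_spring_males_flags_unmated_state(self, fh_haplo):
        state = stable_class_distribution(fh_haplo, TraitState(0.0, 0.5, 0.0))
        assert state.u[SPRING_MALE] == 0.0
        assert state.Q2 == 0.0
        assert state.unmated  # class-3 females face an empty male pool

    def test_exact_replacement_scaling(self, fh_haplo, even_traits):
        # alpha * total autumn daughters per spring female = 1
        state = stable_class_distribution(fh_haplo, even_traits)
        assert state.alpha * state.F_A * (1 - even_traits.z2) == pytest.approx(1.0)


class TestMateCounts:
    def test_symmetric_pools_give_one_mate_each(self):
        cfg = ModelConfig(S_f=0.9, S_m=0.0)
        state = stable_class_distribution(cfg, TraitState(0.5, 0.5, 0.0))
        assert state.Q1 == pytest.approx(1.0)
        assert state.Q2 == pytest.approx(1.0)

    def test_head_count_oracle(self, fh_haplo):
        traits = TraitState(0.5, 0.5, 0.0)
        state = stable_class_distribution(fh_haplo, traits)
        oracle = cohort_head_counts(fh_haplo, traits)
        assert state.Q1 == pytest.approx(oracle["Q1"])
        assert state.Q2 == pytest.approx(oracle["Q2"])

    def test_no_male_survival_shrinks_autumn_pool(self, even_traits):
        full = stable_class_distribution(ModelConfig(S_m=0.6), even_traits)
        none = stable_class_distribution(ModelConfig(S_m=0.0), even_traits)
        assert none.Q1 > full.Q1  # fewer males competing in autumn


class TestHelperEffect:
    def test_no_help_baseline(self, fh_haplo):
        eff = helper_effect(fh_haplo, TraitState(0.5, 0.5, 0.0))
        assert eff.n_helpers == 0.0
        assert eff.F5 == fh_haplo.F1

    def test_boost_arithmetic(self):
        cfg = ModelConfig(F1=5.0, F3=5.0, b=1.5)
        eff = helper_effect(cfg, TraitState(0.0, 0.5, 1.0))
        assert eff.n_helpers == pytest.approx(5.0)
        assert eff.F5 == pytest.approx(5.0 * (1 + 7.5))

    def test_benefit_is_survival_conditioned(self):
        eff = helper_effect(ModelConfig(S_f=0.9, b=1.5), TraitState())
        assert eff.B == pytest.approx(1.35)


class TestGenerationOverlap:
    def test_zero_without_male_survival(self, even_traits):
        state = stable_class_distribution(ModelConfig(S_m=0.0), even_traits)
        assert generation_overlap(state)[0] == 0.0

    def test_fh_overlap_vanishes_without_spring_males(self):
        state = stable_class_distribution(
            ModelConfig(S_m=0.9), TraitState(1e-9, 0.5, 0.0)
        )
        assert generation_overlap(state)[0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_male_survival(self, even_traits):
        oms = [
            generation_overlap(
                stable_class_distribution(ModelConfig(S_m=sm), even_traits)
            )[0]
            for sm in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a < b for a, b in zip(oms, oms[1:]))

    def test_full_overlap_limit(self):
        # surviving spring males monopolize an almost-all-female summer brood
        state = stable_class_distribution(
            ModelConfig(S_m=1.0), TraitState(0.5, 1e-9, 0.0)
        )
        assert generation_overlap(state)[0] == pytest.approx(1.0, abs=1e-6)

    def test_female_overlap_only_for_larval_diapause(self, even_traits):
        fh = stable_class_distribution(ModelConfig(), even_traits)
        ld = stable_class_distribution(ModelConfig(life_cycle="LD"), even_traits)
        assert generation_overlap(fh)[1] == 0.0
        assert generation_overlap(ld)[1] > 0.0
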