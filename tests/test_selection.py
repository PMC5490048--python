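import math

import numpy as np
import pytest

from eusocia.config import ModelConfig, TraitState
from eusocia.selection import (
    SelectionError,
    ThresholdMode,
    closed_form_gradients,
    eusociality_threshold,
    inclusive_fitness_helping,
    inclusive_fitness_sex_ratio,
    relatedness_coefficients,
    resident_state,
    selection_gradient,
    selection_gradients,
    sex_ratio_equilibrium,
    threshold_at_overlap,
)


class TestRelatedness:
    def test_haplodiploid_full_sisters(self):
        rel = relatedness_coefficients(ModelConfig())
        assert rel.r_sis == pytest.approx(3 / 4)
        assert rel.r_bro == pytest.approx(1 / 2)
        assert rel.r_dau == pytest.approx(1 / 2)

    def test_diploid_full_sisters(self):
        rel = relatedness_coefficients(ModelConfig(ploidy="diploid"))
        assert rel.r_sis == pytest.approx(1 / 2)
        assert rel.r_dau == rel.r_son == pytest.approx(1 / 2)

    def test_haplodiploid_two_effective_mates(self):
        rel = relatedness_coefficients(
            ModelConfig(mating="polyandry", m_e=2.0)
        )
        assert rel.r_sis == pytest.approx(1 / 2)  # 1/4 + p/2 with p = 1/2

    def test_diploid_extreme_polyandry_limit(self):
        rel = relatedness_coefficients(
            ModelConfig(ploidy="diploid", mating="polyandry", m_e=1e9)
        )
        assert rel.r_sis == pytest.approx(1 / 4, rel=1e-6)

    def test_serial_monogamy_half_siblings(self):
        rel = relatedness_coefficients(ModelConfig(mating="serial_monogamy"))
        assert rel.r_sis == pytest.approx(1 / 4)
        assert rel.r_bro == pytest.approx(1 / 2)  # brothers stay maternal


class TestGradients:
    @pytest.mark.parametrize(
        "cfg",
        [
            ModelConfig(S_m=0.6, b=1.5),
            ModelConfig(ploidy="diploid", S_m=0.3),
            ModelConfig(life_cycle="LD", S_m=0.6),
            ModelConfig(mating="serial_monogamy", S_m=0.8),
        ],
    )
    def test_finite_difference_matches_closed_form(self, cfg):
        traits = TraitState(0.55, 0.45, 0.2)
        resident = resident_state(cfg, traits)
        closed = closed_form_gradients(cfg, traits, resident)
        for trait_id, expected in zip(
            ("z1", "z2", "h"), closed.as_array()
        ):
            fd = selection_gradient(trait_id, cfg, traits, resident)
            assert fd == pytest.approx(expected, rel=1e-6, abs=1e-8)

    def test_mutant_equal_resident_is_the_baseline(self, fh_haplo):
        traits = TraitState(0.6, 0.4, 0.1)
        resident = resident_state(fh_haplo, traits)
        w0 = inclusive_fitness_sex_ratio(traits, resident)
        w_up = inclusive_fitness_sex_ratio(traits.replace(z1=0.61), resident)
        w_dn = inclusive_fitness_sex_ratio(traits.replace(z1=0.59), resident)
        # fitness is differentiable at the resident: symmetric secants agree
        assert (w_up - w0) / 0.01 == pytest.approx((w0 - w_dn) / 0.01, rel=1e-9)

    def test_symmetric_no_overlap_scenario_is_neutral(self):
        for ploidy in ("haplodiploid", "diploid"):
            cfg = ModelConfig(ploidy=ploidy, S_m=0.0)
            g = selection_gradients(cfg, TraitState(0.5, 0.5, 0.0))
            assert abs(g.dW_dz1) < 1e-9
            assert abs(g.dW_dz2) < 1e-9

    def test_overlap_selects_male_biased_spring_broods(self, fh_haplo):
        g = selection_gradient("z1", fh_haplo, TraitState(0.5, 0.5, 0.0))
        assert g > 1e-4

    def test_helping_never_pays_without_benefit(self):
        cfg = ModelConfig(b=0.0)
        for traits in (TraitState(0.5, 0.5, 0.0), TraitState(0.6, 0.3, 0.4)):
            assert selection_gradient("h", cfg, traits) < 0.0

    def test_unknown_trait_rejected(self, fh_haplo, even_traits):
        with pytest.raises(SelectionError, match="trait_id"):
            selection_gradient("z3", fh_haplo, even_traits)


class TestSexRatioEquilibrium:
    def test_no_overlap_is_unbiased(self):
        assert sex_ratio_equilibrium(ModelConfig(S_m=0.0)) == pytest.approx(
            (0.5, 0.5), abs=1e-6
        )

    def test_fh_overlap_splits_ratios(self, fh_haplo):
        z1, z2 = sex_ratio_equilibrium(fh_haplo)
        assert z1 > 0.5 and z2 < 0.5

    def test_ld_overlap_splits_ratios_the_other_way(self):
        z1, z2 = sex_ratio_equilibrium(ModelConfig(life_cycle="LD", S_m=0.6))
        assert z1 < 0.5 and z2 > 0.5

    def test_summer_rv_ratio_pinned_at_interior_equilibrium(self, fh_haplo):
        # at an interior equilibrium, sons and daughters of the summer brood
        # yield equal life-for-life value: v_m2/v_f2 = r_dau/r_son = 1/2
        from eusocia.reproductive_value import reproductive_values

        z1, z2 = sex_ratio_equilibrium(fh_haplo)
        rvs = reproductive_values(fh_haplo, TraitState(z1, z2, 0.0))
        assert rvs.v_m2 / rvs.v_f2 == pytest.approx(0.5, abs=1e-6)


class TestEusocialityThreshold:
    def test_monogamy_without_overlap_needs_unit_efficiency(self):
        res = eusociality_threshold(ModelConfig(S_m=0.0))
        assert res.B_min == pytest.approx(1.0, abs=1e-5)

    def test_diploid_threshold_ignores_male_survival(self):
        values = [
            eusociality_threshold(
                ModelConfig(ploidy="diploid", S_m=sm)
            ).B_min
            for sm in (0.0, 0.3, 0.6, 0.9)
        ]
        assert np.allclose(values, 1.0, atol=1e-5)

    @pytest.mark.parametrize("m_e, expected", [(2.0, 4 / 3), (3.0, 3 / 2)])
    def test_diploid_polyandry_thresholds(self, m_e, expected):
        res = eusociality_threshold(
            ModelConfig(ploidy="diploid", mating="polyandry", m_e=m_e, S_m=0.5)
        )
        assert res.B_min == pytest.approx(expected, abs=1e-5)

    def test_serial_monogamy_doubles_the_threshold(self):
        res = eusociality_threshold(ModelConfig(mating="serial_monogamy", S_m=0.6))
        assert res.B_min == pytest.approx(2.0, abs=1e-5)

    def test_life_for_life_identity_at_interior_equilibrium(self, fh_haplo):
        # bisection on the helping gradient must land on the closed identity
        # B_min = 2 / (1 + 2 p (1 - z2*)) implied by the pinned RV ratio
        for m_e in (1.0, 1.5, 2.0):
            cfg = fh_haplo if m_e == 1.0 else ModelConfig(
                mating="polyandry", m_e=m_e, S_m=0.6
            )
            res = eusociality_threshold(cfg)
            p = 1.0 / m_e
            expected = 2.0 / (1.0 + 2.0 * p * (1.0 - res.z2_star))
            assert res.B_min == pytest.approx(expected, abs=1e-5)

    def test_threshold_nondecreasing_in_mate_number(self):
        values = [
            eusociality_threshold(
                ModelConfig(mating="polyandry", m_e=m_e, S_m=0.5)
            ).B_min
            for m_e in (1.0, 1.5, 2.0, 4.0, 8.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_larval_diapause_is_harder_than_female_hibernation(self):
        for sm in (0.0, 0.3, 0.6, 0.9):
            fh = eusociality_threshold(ModelConfig(S_m=sm)).B_min
            ld = eusociality_threshold(ModelConfig(life_cycle="LD", S_m=sm)).B_min
            assert ld >= fh - 1e-6

    def test_coevolved_mode_agrees_at_infinitesimal_feedback(self, fh_haplo):
        fixed = eusociality_threshold(fh_haplo, "fixed_sex_ratios").B_min
        coev = eusociality_threshold(fh_haplo, "coevolved_sex_ratios").B_min
        assert coev == pytest.approx(fixed, abs=1e-3)

    def test_missing_sign_change_reports_bracket(self):
        with pytest.raises(SelectionError, match="sign change"):
            eusociality_threshold(
                ModelConfig(mating="serial_monogamy", S_m=0.5),
                bracket=(1e-3, 0.5),
            )


class TestThresholdAtOverlap:
    def test_haplodiploid_limits(self):
        assert threshold_at_overlap(0.0, 1.0) == pytest.approx(1.0)
        assert threshold_at_overlap(1.0, 1.0) == pytest.approx(2 / 3)

    def test_extreme_polyandry_saturates_at_two(self):
        for om in (0.0, 0.5, 1.0 - 1e-9):
            assert threshold_at_overlap(om, 1e6) == pytest.approx(2.0, abs=1e-5)

    def test_sub_unit_thresholds_need_limited_promiscuity(self):
        # B_min < 1 exactly when m_e < 2/(2 - O_m)
        for om in (0.2, 0.6, 0.9):
            frontier = 2.0 / (2.0 - om)
            assert threshold_at_overlap(om, frontier * 0.99) < 1.0
            assert threshold_at_overlap(om, frontier * 1.01) > 1.0

    def test_serial_and_diploid_surfaces(self):
        assert threshold_at_overlap(0.7, mating="serial_monogamy") == 2.0
        assert threshold_at_overlap(0.7, 2.0, ploidy="diploid") == pytest.approx(4 / 3)
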