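"""Macrophage phenotype model, ecological variable and lattice actions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidmac import grid as g
from acidmac.errors import ConfigurationError, ParameterError
from acidmac.macrophage import (
    ANTI_TUMOUR,
    INSENSITIVE,
    PRO_TUMOUR,
    QUEUE_NECROTIC,
    QUEUE_TUMOUR,
    SENSITIVE,
    Macrophage,
    MacrophageParams,
    PhenotypeModel,
    TraitModel,
    act,
    ecological_variable,
    effective_ph,
    maintain_population,
    trait_expression,
    update_behaviour,
)

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestEcologicalVariable:
    @pytest.mark.parametrize(
        "abcd,expected",
        [
            ((1, 1, 0, 0), -1.0),   # extreme inflammatory, tumour-rich milieu
            ((0, 0, 1, 1), +1.0),   # extreme anti-inflammatory, necrotic milieu
            ((1, 1, 1, 1), 0.0),    # symmetric cancellation
            ((0, 0, 0, 0), 0.0),
        ],
    )
    def test_exact_values(self, abcd, expected):
        assert ecological_variable(*abcd) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [(-0.1, 0, 0, 0), (0, 1.2, 0, 0), (0, 0, 0, 2)])
    def test_inputs_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ParameterError):
            ecological_variable(*bad)

    @given(unit, unit, unit, unit)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_matches_direct_formula(self, a, b, c, d):
        e = ecological_variable(a, b, c, d)
        assert -1.0 <= e <= 1.0
        assert e == -0.5 * a - 0.5 * b + 0.5 * c + 0.5 * d


def model_of(*traits):
    return PhenotypeModel(list(traits))


class TestTraitExpression:
    def test_constant_model(self):
        m = model_of(TraitModel("t", ANTI_TUMOUR, 1.0, 0.0, 0.0, 0.0, 0, 1))
        assert trait_expression(m, "t", 6.2, -0.7) == 1.0

    def test_pure_ph_term(self):
        m = model_of(TraitModel("t", ANTI_TUMOUR, 0.0, 1.0, 0.0, 0.0, 0, 1))
        assert trait_expression(m, "t", 6.8, 0.42) == pytest.approx(6.8)

    def test_full_linear_form_hand_value(self):
        # 2 + (-0.1)(7.4) + (1)(-1) + (0.05)(7.4)(-1) = -0.11
        m = model_of(TraitModel("t", ANTI_TUMOUR, 2.0, -0.1, 1.0, 0.05, 0, 1))
        assert trait_expression(m, "t", 7.4, -1.0) == pytest.approx(-0.11, abs=1e-12)

    def test_unknown_trait_raises(self):
        m = model_of(TraitModel("t", ANTI_TUMOUR, 1, 0, 0, 0, 0, 1))
        with pytest.raises(KeyError):
            trait_expression(m, "nope", 7.4, 0.0)

    def test_empty_trait_set_rejected(self):
        with pytest.raises(ConfigurationError):
            PhenotypeModel([])


class TestEffectivePh:
    @pytest.mark.parametrize(
        "local,scenario,expected",
        [(6.6, INSENSITIVE, 7.4), (6.6, SENSITIVE, 6.6),
         (7.4, SENSITIVE, 7.4), (7.4, INSENSITIVE, 7.4)],
    )
    def test_scenarios(self, local, scenario, expected):
        assert effective_ph(local, scenario) == expected

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ParameterError):
            effective_ph(7.0, "agnostic")


class TestUpdateBehaviour:
    def test_symmetric_constant_traits_give_zero_behaviour(self, mac_params):
        m = model_of(
            TraitModel("anti", ANTI_TUMOUR, 0.5, 0, 0, 0, 0.0, 1.0),
            TraitModel("pro", PRO_TUMOUR, 0.5, 0, 0, 0, 0.0, 1.0),
        )
        mac = Macrophage(position=(0, 0))
        update_behaviour(mac, m, 6.5, 0.0, 0.0, SENSITIVE, mac_params)
        assert mac.behaviour == pytest.approx(0.0, abs=1e-14)

    def test_no_ph_terms_makes_scenarios_identical(self, mac_params):
        m = model_of(
            TraitModel("anti", ANTI_TUMOUR, 1.0, 0.0, -2.0, 0.0, -3, 3),
            TraitModel("pro", PRO_TUMOUR, 1.0, 0.0, 2.0, 0.0, -3, 3),
        )
        outs = []
        for scenario in (SENSITIVE, INSENSITIVE):
            mac = Macrophage(position=(0, 0))
            update_behaviour(mac, m, 6.3, 0.4, 0.1, scenario, mac_params)
            outs.append(mac.behaviour)
        assert outs[0] == pytest.approx(outs[1], abs=1e-14)

    def test_behaviour_increases_with_ecological_variable(self, mac_params):
        """With a pro-trait rising in e and an anti-trait falling in e the
        behaviour scalar is strictly increasing as the milieu shifts from
        inflammatory to anti-inflammatory."""
        m = model_of(
            TraitModel("anti", ANTI_TUMOUR, 1.0, 0.0, -1.0, 0.0, -3, 3),
            TraitModel("pro", PRO_TUMOUR, 1.0, 0.0, 1.0, 0.0, -3, 3),
        )
        behaviours = []
        for anti_cyt in np.linspace(0.0, 5.0, 8):  # raises c, hence e
            mac = Macrophage(position=(0, 0))
            update_behaviour(mac, m, 7.4, 0.0, float(anti_cyt), SENSITIVE, mac_params)
            behaviours.append(mac.behaviour)
        assert np.all(np.diff(behaviours) > 0)

    def test_digestion_queue_enters_b_and_d(self, mac_params):
        m = model_of(TraitModel("anti", ANTI_TUMOUR, 0.5, 0, 0, 0, 0, 1))
        mac = Macrophage(position=(0, 0))
        mac.digestion_queue = [[QUEUE_TUMOUR, 3.0], [QUEUE_NECROTIC, 3.0],
                               [QUEUE_NECROTIC, 1.0]]
        update_behaviour(mac, m, 7.4, 0.0, 0.0, SENSITIVE, mac_params)
        assert mac.eco.b == pytest.approx(1 / mac_params.capacity)
        assert mac.eco.d == pytest.approx(2 / mac_params.capacity)


def _arena(code_at=None):
    occ = np.zeros((5, 5), dtype=np.int8)
    if code_at:
        for pos, code in code_at.items():
            occ[pos] = code
    return occ, np.zeros((5, 5), dtype=bool)


class TestAct:
    def test_fully_pro_tumour_macrophage_never_engulfs_tumour(self, mac_params, rng):
        occ, mocc = _arena({(2, 1): g.TUMOUR})
        mac = Macrophage(position=(2, 2), behaviour=+1.0)
        fields = {"pro_cytokine": np.zeros((5, 5)), "anti_cytokine": np.zeros((5, 5))}
        for _ in range(30):
            act(mac, occ, mocc, fields, mac_params, rng)
        assert occ[2, 1] == g.TUMOUR
        assert mac.queue_count(QUEUE_TUMOUR) == 0

    def test_forced_engulfment_of_adjacent_tumour(self, rng):
        p = MacrophageParams(p_kill=1.0)
        occ, mocc = _arena({(2, 1): g.TUMOUR})
        mac = Macrophage(position=(2, 2), behaviour=-1.0)
        fields = {"pro_cytokine": np.zeros((5, 5)), "anti_cytokine": np.zeros((5, 5))}
        summary = act(mac, occ, mocc, fields, p, rng)
        assert summary["engulfed_tumour"] == 1
        assert occ[2, 1] == g.EMPTY
        assert mac.queue_count(QUEUE_TUMOUR) == 1

    def test_full_queue_blocks_engulfment(self, rng):
        p = MacrophageParams(p_kill=1.0, capacity=2)
        occ, mocc = _arena({(2, 1): g.TUMOUR})
        mac = Macrophage(position=(2, 2), behaviour=-1.0)
        mac.digestion_queue = [[QUEUE_TUMOUR, 99.0], [QUEUE_TUMOUR, 99.0]]
        fields = {"pro_cytokine": np.zeros((5, 5)), "anti_cytokine": np.zeros((5, 5))}
        summary = act(mac, occ, mocc, fields, p, rng)
        assert summary["engulfed_tumour"] == 0
        assert occ[2, 1] == g.TUMOUR

    def test_secretion_sign_follows_behaviour(self, mac_params, rng):
        fields = {"pro_cytokine": np.zeros((5, 5)), "anti_cytokine": np.zeros((5, 5))}
        occ, mocc = _arena()
        anti_mac = Macrophage(position=(1, 1), behaviour=-1.0)
        act(anti_mac, occ, mocc, fields, mac_params, rng)
        assert fields["pro_cytokine"][1, 1] == pytest.approx(mac_params.s_pro)
        assert fields["anti_cytokine"][1, 1] == 0.0
        pro_mac = Macrophage(position=(3, 3), behaviour=+1.0)
        act(pro_mac, occ, mocc, fields, mac_params, rng)
        assert fields["anti_cytokine"][3, 3] == pytest.approx(mac_params.s_anti)

    def test_digestion_completes_after_digestion_time(self, rng):
        p = MacrophageParams(digestion_time=2.0, p_move=0.0)
        occ, mocc = _arena()
        mac = Macrophage(position=(2, 2), behaviour=0.0)
        mac.digestion_queue = [[QUEUE_TUMOUR, 2.0]]
        fields = {"pro_cytokine": np.zeros((5, 5)), "anti_cytokine": np.zeros((5, 5))}
        act(mac, occ, mocc, fields, p, rng)
        assert len(mac.digestion_queue) == 1
        act(mac, occ, mocc, fields, p, rng)
        assert len(mac.digestion_queue) == 0
        assert mac.digested_count == 1


class TestMaintainPopulation:
    def test_no_change_when_at_target(self, rng):
        occ = np.full((6, 6), g.NORMAL, dtype=np.int8)
        occ[0, 0] = g.VESSEL
        mocc = np.zeros((6, 6), dtype=bool)
        macs = [Macrophage(position=(3, 3))]
        mocc[3, 3] = True
        out = maintain_population(occ, mocc, macs, 1, rng)
        assert len(out) == 1

    def test_deficit_filled_with_naive_macrophages(self, rng):
        occ = np.full((6, 6), g.NORMAL, dtype=np.int8)
        occ[2, 2] = g.VESSEL
        mocc = np.zeros((6, 6), dtype=bool)
        macs = maintain_population(occ, mocc, [], 2, rng)
        assert len(macs) == 2
        for m in macs:
            assert m.behaviour == 0.0 and not m.digestion_queue
            assert mocc[m.position]

    def test_target_zero_is_macrophage_free(self, rng):
        occ = np.full((6, 6), g.NORMAL, dtype=np.int8)
        mocc = np.zeros((6, 6), dtype=bool)
        assert maintain_population(occ, mocc, [], 0, rng) == []

    def test_negative_target_rejected(self, rng):
        occ = np.zeros((4, 4), dtype=np.int8)
        with pytest.raises(ParameterError):
            maintain_population(occ, np.zeros((4, 4), bool), [], -1, rng)
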