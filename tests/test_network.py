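"""Network construction, dose forcing and mass-action flux evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhejkin import (
    REYNOLDS_LIKE_PARAMS,
    DoseSchedule,
    ParameterSet,
    build_network,
    dose_indicator,
    evaluate_fluxes,
)
from nhejkin.network import species_for

P = REYNOLDS_LIKE_PARAMS


@pytest.mark.parametrize(
    "variant,n_species,n_reactions",
    [("SF1", 12, 12), ("SF2", 12, 12), ("SF3", 11, 11), ("BF", 12, 12)],
)
def test_variant_shapes(variant, n_species, n_reactions):
    net = build_network(variant, P)
    assert net.n_species == n_species
    assert net.n_reactions == n_reactions
    assert net.SM.shape == (n_species, n_reactions)
    # repaired bookkeeping pools exist in every variant
    assert {"RS", "RC"} <= set(net.species)


def test_bf_has_no_second_order_reactions():
    net = build_network("BF", P)
    assert all(r.order != "second_self" for r in net.reactions)


def test_sf3_is_sf1_without_the_paired_unprocessed_stage():
    sf1, sf3 = species_for("SF1"), species_for("SF3")
    assert set(sf1) - set(sf3) == {"C2"}
    # and the merged reaction goes straight from bound ends to processed synapsis
    net = build_network("SF3", P)
    merged = [r for r in net.reactions if r.param == "k_EPL"]
    assert len(merged) == 1 and merged[0].reactant == "C1" and merged[0].products == (("C3", 1),)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown model variant"):
        build_network("SF9", P)


def test_nonpositive_rate_rejected_with_name():
    with pytest.raises(ValueError, match="k_LK"):
        build_network("SF1", P.updated(k_LK=0.0))


def test_zero_production_rate_is_allowed():
    net = build_network("SF1", P.updated(b_C=0.0))
    assert net.n_reactions == 12


def test_inhibited_members_default_to_control():
    p = ParameterSet(b_S=1, b_C=1, k_a1=1, k_LK=1, k_LD=1, k_d1=1, k_d2=1, k_EP=1, k_pD=0.3)
    assert p.value("k_pD_i") == 0.3
    net = build_network("SF1", p, condition="inhibited")
    (rel,) = [r for r in net.reactions if r.name == "dnapk_release"]
    assert rel.param == "k_pD_i"


def test_parameterset_rejects_unknown_names():
    with pytest.raises(ValueError, match="unknown parameter"):
        ParameterSet.from_dict({"k_zz": 1.0})


class TestDoseIndicator:
    def test_acute_window(self):
        sched = DoseSchedule.acute(0.5)
        assert dose_indicator(0.25, sched) == 1
        assert dose_indicator(1.0, sched) == 0
        # right-open window: forcing is off exactly at T_R
        assert dose_indicator(0.5, sched) == 0
        assert dose_indicator(0.0, sched) == 1

    def test_fractionated_windows(self):
        sched = DoseSchedule.fractionated([0.0, 0.5, 10.0, 10.5])
        assert [dose_indicator(t, sched) for t in (0.2, 5.0, 10.2, 11.0)] == [1, 0, 1, 0]
        assert sched.exposure_time == 1.0
        assert sched.integrated_exposure(10.25) == pytest.approx(0.75)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule.fractionated([0.0, 0.5, 0.5])
        with pytest.raises(ValueError):
            DoseSchedule.fractionated([0.0, 0.5, 1.0])  # odd count


class TestFluxes:
    def test_all_zero_state_after_exposure_gives_zero_fluxes(self):
        net = build_network("SF1", P)
        assert np.allclose(evaluate_fluxes(net, np.zeros(12), 1.0), 0.0)

    def test_second_order_flux_and_two_for_one_stoichiometry(self):
        net = build_network("SF1", P.updated(k_LK=0.1))
        x = np.zeros(12)
        x[net.index("S1")] = 2.0
        fluxes = evaluate_fluxes(net, x, 1.0)
        (j,) = [j for j, r in enumerate(net.reactions) if r.name == "simple_synapsis"]
        assert fluxes[j] == pytest.approx(0.4)  # k * S1^2
        dx = net.SM @ fluxes
        assert dx[net.index("S1")] == pytest.approx(-0.8)  # two ends consumed per event
        assert dx[net.index("S2")] == pytest.approx(0.4)

    def test_negative_state_rejected(self):
        net = build_network("SF1", P)
        x = np.zeros(12)
        x[3] = -1e-3
        with pytest.raises(ValueError, match="negative concentration"):
            evaluate_fluxes(net, x, 1.0)

    def test_sf1_derivative_matches_hand_assembled_rate_equations(self):
        """SM @ R equals the rate equations written out term by term."""
        net = build_network("SF1", P)
        q = {nm: P.value(nm) for nm in
             ("b_S", "b_C", "k_a1", "k_LK", "k_LD", "k_d1", "k_d2", "k_EP", "k_pD")}
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = dict(zip(net.species, rng.uniform(0, 5, 12)))
            for t, u in ((0.25, 1.0), (3.0, 0.0)):
                expected = {
                    "S0": q["b_S"] * u - q["k_a1"] * x["S0"],
                    "S1": q["k_a1"] * x["S0"] - 2 * q["k_LK"] * x["S1"] ** 2,
                    "S2": q["k_LK"] * x["S1"] ** 2 - q["k_d1"] * x["S2"],
                    "S3": q["k_d1"] * x["S2"] - q["k_d2"] * x["S3"],
                    "RS": q["k_d2"] * x["S3"],
                    "C0": q["b_C"] * u - q["k_a1"] * x["C0"],
                    "C1": q["k_a1"] * x["C0"] - 2 * q["k_LD"] * x["C1"] ** 2,
                    "C2": q["k_LD"] * x["C1"] ** 2 - q["k_EP"] * x["C2"],
                    "C3": q["k_EP"] * x["C2"] - q["k_a1"] * x["C3"],
                    "C4": q["k_a1"] * x["C3"] - q["k_pD"] * x["C4"],
                    "C5": q["k_pD"] * x["C4"] - q["k_d2"] * x["C5"],
                    "RC": q["k_d2"] * x["C5"],
                }
                xv = np.array([x[s] for s in net.species])
                dx = net.SM @ evaluate_fluxes(net, xv, t)
                np.testing.assert_allclose(
                    dx, [expected[s] for s in net.species], rtol=1e-12, atol=1e-12
                )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        alpha=st.floats(0.01, 100.0),
        values=st.lists(st.floats(0.0, 10.0), min_size=12, max_size=12),
    )
    def test_bf_fluxes_are_linear_in_state_after_exposure(self, alpha, values):
        net = build_network("BF", P)
        x = np.array(values)
        f1 = evaluate_fluxes(net, alpha * x, 2.0)
        f2 = alpha * evaluate_fluxes(net, x, 2.0)
        np.testing.assert_allclose(f1, f2, rtol=1e-9, atol=1e-12)


def test_end_conservation_is_built_into_the_stoichiometry():
    """Every non-production reaction conserves the end count; production adds 1."""
    for variant in ("SF1", "SF2", "SF3"):
        net = build_network(variant, P)
        w = net.end_weights()
        net_change = w @ net.SM  # per-reaction end change
        for j, r in enumerate(net.reactions):
            assert net_change[j] == pytest.approx(1.0 if r.order == "zero" else 0.0)
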