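"""Trajectory integration, observables, conservation and limiting behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhejkin import (
    REYNOLDS_LIKE_PARAMS,
    DoseSchedule,
    Trajectory,
    build_network,
    dnapkcs_signal,
    integrate,
    ku_signal,
    normalize,
)

P = REYNOLDS_LIKE_PARAMS


def make_traj(variant="SF1", condition="control", t_end=180.5, params=P, **kw):
    net = build_network(variant, params, condition=condition)
    return integrate(net, t_end=t_end, **kw), net


def test_no_source_gives_identically_zero_trajectory():
    traj, _ = make_traj(params=P.updated(b_S=0.0, b_C=0.0), t_end=30.0)
    assert np.all(traj.states == 0.0)


@pytest.mark.parametrize("variant", ["SF1", "SF2", "SF3"])
def test_end_conservation_along_trajectory(variant):
    """Singles + 2*(synapses + repaired) equals the integrated end source."""
    net = build_network(variant, P)
    traj = integrate(net, t_end=120.5)
    w = net.end_weights()
    total = traj.states @ w
    expected = np.array([net.produced_total(t) for t in traj.times])
    final = net.produced_total(traj.times[-1])
    np.testing.assert_allclose(total, expected, atol=1e-6 * final)


def test_bf_break_conservation_with_ends_convention():
    """In ends mode each break absorbs two produced ends."""
    net = build_network("BF", P, breaks_mode="ends")
    traj = integrate(net, t_end=60.5)
    total = traj.states.sum(axis=1)
    assert net.produced_total(traj.times[-1]) == pytest.approx((P.b_S + P.b_C) * 0.5 / 2)
    np.testing.assert_allclose(
        total, [net.produced_total(t) for t in traj.times], atol=1e-6 * total[-1]
    )


def test_repaired_pool_is_monotone_nondecreasing():
    traj, _ = make_traj()
    repaired = traj["RS"] + traj["RC"]
    assert np.all(np.diff(repaired) >= -1e-9)


class TestObservables:
    def test_released_species_carry_no_signal(self):
        net = build_network("SF1", P)
        x = np.zeros(12)
        x[net.index("S3")] = 5.0
        x[net.index("C5")] = 3.0
        assert ku_signal(x, net) == 0.0
        assert dnapkcs_signal(x, net) == 0.0

    def test_per_end_weighting(self):
        net = build_network("SF1", P)
        x = np.zeros(12)
        x[net.index("S1")] = 1.0  # one tagged end
        x[net.index("S2")] = 1.0  # synapsis: two tagged ends
        assert ku_signal(x, net) == pytest.approx(3.0)
        x = np.zeros(12)
        x[net.index("C1")] = 2.0
        x[net.index("C2")] = 1.0
        assert dnapkcs_signal(x, net) == pytest.approx(4.0)

    def test_simple_pathway_species_have_no_dnapkcs(self):
        net = build_network("SF1", P)
        x = np.zeros(12)
        for s in ("S0", "S1", "S2", "S3", "RS"):
            x[net.index(s)] = 2.0
        assert dnapkcs_signal(x, net) == 0.0

    def test_xl_release_rate_does_not_affect_observables(self):
        """K and D live upstream of the k_d2 step; x10 change leaves them intact."""
        t1, _ = make_traj("SF1", rtol=1e-10, atol=1e-12)
        t2, _ = make_traj("SF1", params=P.updated(k_d2=P.k_d2 * 10), rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(t1.K, t2.K, rtol=0, atol=1e-8)
        np.testing.assert_allclose(t1.D, t2.D, rtol=0, atol=1e-8)

    def test_simple_chain_rates_do_not_affect_dnapkcs(self):
        """Simple and complex pathways are uncoupled, so D ignores k_LK, k_d1."""
        t1, _ = make_traj("SF1", rtol=1e-10, atol=1e-12)
        t2, _ = make_traj(
            "SF1", params=P.updated(k_LK=P.k_LK * 4, k_d1=P.k_d1 / 3), rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(t1.D, t2.D, rtol=0, atol=1e-8)


class TestNormalize:
    def test_examples(self):
        np.testing.assert_allclose(normalize(np.array([5.0, 5.0, 5.0])), 1.0)
        np.testing.assert_allclose(normalize(np.array([0, 2, 4, 1.0])), [0, 0.5, 1, 0.25])

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError, match="positive maximum"):
            normalize(np.zeros(4))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, alpha):
        y = np.array([0.1, 1.0, 0.4, 0.2])
        np.testing.assert_allclose(normalize(alpha * y), normalize(y), rtol=1e-12)

    def test_trajectory_normalized_peak_is_one(self, sf1_true_curves):
        assert sf1_true_curves["control"].K_hat.max() == 1.0
        assert sf1_true_curves["control"].D_hat.max() == 1.0


def test_long_horizon_complete_repair():
    """With fast synapsis rates everything ends up in the repaired pools."""
    params = P.updated(k_LK=5.0, k_LD=5.0, k_EPL=5.0)
    for variant in ("SF1", "SF2", "SF3", "BF"):
        net = build_network(variant, params)
        grid = np.array([0.0, 0.5, 1.0, 10.0, 100.0, 1e3, 1e4])
        traj = integrate(net, t_end=1e4, grid=grid)
        w = net.end_weights()
        total = float(traj.states[-1] @ w)
        ir = [net.index("RS"), net.index("RC")]
        unrepaired = total - float(w[ir] @ traj.states[-1][ir])
        assert unrepaired < 1e-6 * total


def test_merging_limit_sf1_to_sf3():
    """Fast end processing collapses the synapsis+processing pair to one step."""
    p1 = P.updated(k_EP=1000 * P.k_LD)
    p3 = P.updated(k_EPL=P.k_LD)
    t1, _ = make_traj("SF1", params=p1)
    t3, _ = make_traj("SF3", params=p3)
    for ch in ("Ku", "DNAPKcs"):
        a = t1.interp(ch, t3.times)
        b = t3.signal(ch)
        assert np.max(np.abs(a - b)) < 0.02


def test_biphasic_log_decay_is_convex_after_peak(sf1_true_curves):
    """Fast simple-DSB loss then slow complex-DSB loss: log K convex in t."""
    traj = sf1_true_curves["control"]
    t = np.linspace(5.0, 180.0, 60)
    logK = np.log(np.interp(t, traj.times, traj.K))
    assert np.all(np.diff(logK) < 0)  # decaying after the peak
    assert np.all(np.diff(logK, 2) >= -1e-6)  # convex: fast phase first


def test_trajectory_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((3, 2)), ["S0", "S1"], "SF1")
    with pytest.raises(ValueError, match="shape"):
        Trajectory(np.array([0.0, 1.0]), np.zeros((2, 3)), ["S0", "S1"], "SF1")


def test_grid_outside_span_rejected():
    net = build_network("SF1", P)
    with pytest.raises(ValueError, match="grid"):
        integrate(net, t_end=10.0, grid=np.array([0.0, 20.0]))


def test_fractionated_schedule_produces_two_recruitment_waves():
    sched = DoseSchedule.fractionated([0.0, 0.5, 60.0, 60.5])
    net = build_network("SF1", P, schedule=sched)
    traj = integrate(net, sched, t_end=120.0)
    K = traj.K
    t = traj.times
    first = K[(t > 0.5) & (t < 50)].max()
    trough = K[(t > 55) & (t < 60)].min()
    second = K[(t > 60.5) & (t < 110)].max()
    assert second > trough  # the second pulse re-raises the signal
    assert first > 0 and second > 0
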