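"""Error functions: channel misfit, the 4-quadrant total, and their invariances."""

import numpy as np
import pytest

from nhejkin import (
    REYNOLDS_LIKE_PARAMS,
    KineticDataset,
    Trajectory,
    channel_error,
    error_components,
    total_error,
)

P = REYNOLDS_LIKE_PARAMS


def toy_trajectory():
    """SF1 trajectory whose K_hat is exactly [0, 1, 0.5, 0.25] on t = 0..3."""
    times = np.array([0.0, 1.0, 2.0, 3.0])
    states = np.zeros((4, 12))
    species = ["S0", "S1", "S2", "S3", "C0", "C1", "C2", "C3", "C4", "C5", "RS", "RC"]
    states[:, species.index("S1")] = [0.0, 4.0, 2.0, 1.0]
    return Trajectory(times, states, species, "SF1")


def test_perfect_fit_has_zero_error():
    traj = toy_trajectory()
    ds = KineticDataset("Ku", "control", [1.0, 2.0], [1.0, 0.5])
    assert channel_error(traj, ds) == 0.0


def test_three_four_five_residuals():
    traj = toy_trajectory()
    # model K_hat at t=2,3 is (0.5, 0.25); residuals 0.3 and 0.4
    ds = KineticDataset("Ku", "control", [2.0, 3.0], [0.2, 0.65])
    assert channel_error(traj, ds, "l2") == pytest.approx(0.5)
    assert channel_error(traj, ds, "lsq") == pytest.approx(0.25)


def test_l2_is_root_of_least_squares():
    traj = toy_trajectory()
    ds = KineticDataset("Ku", "control", [0.5, 1.5, 2.5], [0.3, 0.9, 0.1])
    assert channel_error(traj, ds, "l2") == pytest.approx(
        np.sqrt(channel_error(traj, ds, "lsq"))
    )


def test_data_time_beyond_grid_rejected():
    traj = toy_trajectory()
    ds = KineticDataset("Ku", "control", [2.0, 4.0], [0.5, 0.2])
    with pytest.raises(ValueError, match="outside"):
        channel_error(traj, ds)


def test_noiseless_bundle_gives_zero_total_error(sf3_noiseless_bundle):
    assert total_error(P, "SF3", sf3_noiseless_bundle) < 1e-8


def test_missing_quadrant_rejected(sf3_noiseless_bundle):
    with pytest.raises(ValueError, match="missing dataset quadrant"):
        total_error(P, "SF3", sf3_noiseless_bundle[:3])


def test_duplicated_conditions_double_the_error(sf1_noisy_bundle):
    """With inhibited data == control data and k_pD_i = k_pD, E = 2(E_K + E_D)."""
    by_key = {ds.key(): ds for ds in sf1_noisy_bundle}
    dup = []
    for ds in (by_key[("Ku", "control")], by_key[("DNAPKcs", "control")]):
        dup.append(ds)
        dup.append(KineticDataset(ds.channel, "inhibited", ds.times, ds.values))
    p = P.updated(k_pD_i=P.k_pD)
    comp = error_components(p, "SF1", dup)
    assert comp["E_K_i"] == pytest.approx(comp["E_K"], rel=1e-9)
    assert comp["E_D_i"] == pytest.approx(comp["E_D"], rel=1e-9)
    assert comp["E"] == pytest.approx(2 * (comp["E_K"] + comp["E_D"]), rel=1e-9)


def test_error_invariant_to_bundle_ordering(sf1_noisy_bundle):
    e1 = total_error(P, "SF1", sf1_noisy_bundle)
    e2 = total_error(P, "SF1", list(reversed(sf1_noisy_bundle)))
    assert e1 == e2


def test_error_invariant_to_xl_release_rate(sf1_noisy_bundle):
    """E does not move across a decade of k_d2 values."""
    base = total_error(P, "SF1", sf1_noisy_bundle, rtol=1e-10, atol=1e-12)
    for f in np.linspace(0.1, 10, 10):
        e = total_error(P.updated(k_d2=P.k_d2 * f), "SF1", sf1_noisy_bundle,
                        rtol=1e-10, atol=1e-12)
        assert e == pytest.approx(base, abs=1e-8)


def test_error_is_positive_unless_perfect(sf1_noisy_bundle):
    assert total_error(P, "SF1", sf1_noisy_bundle) > 0
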