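"""Synthetic bundle generator: determinism, noise model, preset shape."""

import numpy as np
import pytest
from scipy.stats import norm

from nhejkin import REYNOLDS_LIKE_PARAMS, ZeroSignalError, generate_bundle, total_error
from nhejkin.data import write_bundle_csv
from nhejkin.synthetic import (
    GeneratorSpec,
    reynolds_like_preset,
    sample_bundle,
    simulate_true_curves,
)

P = REYNOLDS_LIKE_PARAMS


def test_noiseless_bundle_lies_on_the_model_curves(sf3_noiseless_bundle):
    assert total_error(P, "SF3", sf3_noiseless_bundle) < 1e-8


def test_same_seed_gives_byte_identical_csvs(tmp_path):
    spec = reynolds_like_preset(sigma=0.05, seed=123)
    for name in ("a.csv", "b.csv"):
        write_bundle_csv(tmp_path / name, generate_bundle(spec))
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_different_seeds_differ():
    b1 = generate_bundle(reynolds_like_preset(sigma=0.05, seed=1))
    b2 = generate_bundle(reynolds_like_preset(sigma=0.05, seed=2))
    assert not np.array_equal(b1[0].values, b2[0].values)


def test_replicate_mean_matches_truncated_gaussian_expectation():
    """Across replicates the sample mean follows E[max(0, mu + sigma Z)]."""
    spec = reynolds_like_preset(variant="SF3", sigma=0.05, seed=0)
    trajs = simulate_true_curves(spec)
    mu = trajs["control"].interp("Ku", spec.model_times("Ku"))
    n_rep = 200
    draws = np.empty((n_rep, mu.size))
    for k in range(n_rep):
        bundle = sample_bundle(trajs, GeneratorSpec(
            variant=spec.variant, p_true=spec.p_true, sigma=spec.sigma, seed=10_000 + k))
        ku_control = [d for d in bundle if d.key() == ("Ku", "control")][0]
        draws[k] = ku_control.values
    s = spec.sigma
    z = mu / s
    expected = mu * norm.cdf(z) + s * norm.pdf(z)  # censored-at-zero mean
    se = s / np.sqrt(n_rep)
    assert np.all(np.abs(draws.mean(axis=0) - expected) < 2.5 * se)


def test_bundle_has_all_four_quadrants_with_provenance(sf3_noiseless_bundle):
    keys = {ds.key() for ds in sf3_noiseless_bundle}
    assert keys == {("Ku", "control"), ("Ku", "inhibited"),
                    ("DNAPKcs", "control"), ("DNAPKcs", "inhibited")}
    for ds in sf3_noiseless_bundle:
        assert ds.provenance["synthetic"] is True
        assert "seed" in ds.provenance and "p_true" in ds.provenance


class TestPresetShape:
    def test_ku_peak_within_two_minutes_of_irradiation_end(self, sf1_true_curves):
        traj = sf1_true_curves["control"]
        t_peak = traj.times[np.argmax(traj.K)]
        assert t_peak <= 0.5 + 2.0

    def test_dnapkcs_retention_under_atm_inhibition(self, sf1_true_curves):
        c = sf1_true_curves["control"].interp("DNAPKcs", [120.5])[0]
        i = sf1_true_curves["inhibited"].interp("DNAPKcs", [120.5])[0]
        assert i > c

    def test_preset_satisfies_the_qualitative_orderings(self):
        spec = reynolds_like_preset()
        assert spec.p_true.value("k_LD") < spec.p_true.value("k_LK")
        assert spec.p_true.value("k_pD_i") < spec.p_true.value("k_pD") / 5


def test_no_complex_pathway_flags_zero_dnapkcs_signal():
    spec = reynolds_like_preset()
    spec = GeneratorSpec(variant=spec.variant, p_true=spec.p_true.updated(b_C=0.0))
    with pytest.raises(ZeroSignalError, match="DNAPKcs"):
        generate_bundle(spec)


def test_no_damage_at_all_rejected():
    spec = GeneratorSpec(p_true=P.updated(b_S=0.0, b_C=0.0))
    with pytest.raises(ZeroSignalError):
        generate_bundle(spec)


def test_negative_sigma_rejected():
    with pytest.raises(ValueError, match="sigma"):
        GeneratorSpec(sigma=-0.1)


def test_grid_sizes_and_clock_shift():
    spec = reynolds_like_preset()
    assert len(spec.ku_times) == 13 and max(spec.ku_times) == 120
    assert len(spec.dnapkcs_times) == 15 and max(spec.dnapkcs_times) == 180
    assert spec.model_times("Ku")[0] == pytest.approx(0.5)  # +T_R shift
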