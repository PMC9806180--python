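"""Split-half / test-retest consistency, Fisher pooling, bootstraps."""

import numpy as np
import pandas as pd
import pytest

import idiobias as ib
from idiobias import consistency as cons
from idiobias.errors import matching_errors, rating_errors


def _one_observer_frame(keys, errors):
    return pd.DataFrame(
        {
            "observer_id": "o",
            "group": "radiologist",
            "stim_bin": keys,
            "error": errors,
        }
    )


@pytest.mark.parametrize("seed", range(10))
def test_split_half_two_trials_always_one_each(seed):
    df = _one_observer_frame([0, 0, 1, 1], [1.0, 3.0, -2.0, 4.0])
    a, b = ib.split_half(df, n_keys=2, seed=seed)
    assert list(a.n_trials) == [1, 1]
    assert list(b.n_trials) == [1, 1]
    np.testing.assert_allclose(
        a.errors.to_numpy() + b.errors.to_numpy(), [4.0, 2.0]
    )


@pytest.mark.parametrize("seed", range(10))
def test_split_half_odd_count_splits_near_equal(seed):
    df = _one_observer_frame([0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
    a, b = ib.split_half(df, n_keys=1, seed=seed)
    assert sorted([int(a.n_trials[0]), int(b.n_trials[0])]) == [2, 3]


def test_split_half_deterministic_and_single_trial_key():
    df = _one_observer_frame([0, 0, 1], [1.0, 2.0, 7.0])
    a1, b1 = ib.split_half(df, n_keys=2, seed=5)
    a2, b2 = ib.split_half(df, n_keys=2, seed=5)
    pd.testing.assert_series_equal(a1.errors, a2.errors)
    pd.testing.assert_series_equal(b1.errors, b2.errors)
    # the lone trial of key 1 lands in exactly one half
    assert (1 in a1.errors.index) != (1 in b1.errors.index)


def test_profile_correlation_examples():
    a = pd.Series([1.0, 2.0, 3.0])
    assert ib.profile_correlation(a, a) == pytest.approx(1.0)
    assert ib.profile_correlation(a, -a) == pytest.approx(-1.0)
    b = pd.Series([1.0, 2.0, 4.0])
    # hand-computed Pearson for [1,2,3] vs [1,2,4]
    assert ib.profile_correlation(a, b) == pytest.approx(0.98198, abs=1e-5)


def test_profile_correlation_requires_shared_keys_and_variance():
    a = pd.Series([1.0, 2.0], index=[0, 1])
    b = pd.Series([1.0, 2.0], index=[0, 1])
    with pytest.raises(ValueError):
        ib.profile_correlation(a, b)
    c = pd.Series([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        ib.profile_correlation(c, pd.Series([1.0, 2.0, 3.0]))


def test_profile_correlation_pairwise_complete():
    a = pd.Series([1.0, 2.0, 3.0, 9.0], index=[0, 1, 2, 3])
    b = pd.Series([1.0, 2.0, 3.0, -5.0], index=[0, 1, 2, 9])
    assert ib.profile_correlation(a, b) == pytest.approx(1.0)


def test_fisher_z_examples_and_round_trip():
    assert ib.fisher_z(0.0) == 0.0
    assert ib.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
    assert ib.fisher_z(-0.7) == -ib.fisher_z(0.7)
    for r in (-0.9, -0.2, 0.0, 0.4, 0.99):
        assert ib.inverse_fisher_z(ib.fisher_z(r)) == pytest.approx(r)
    with pytest.raises(ValueError):
        ib.fisher_z(1.0)


def test_pool_correlations():
    assert ib.pool_correlations([0.5, 0.5]) == pytest.approx(0.5)
    assert ib.pool_correlations([0.0, 0.8]) == pytest.approx(0.5, abs=1e-4)
    assert ib.pool_correlations([0.1, 0.6, -0.3]) == pytest.approx(
        ib.pool_correlations([-0.3, 0.1, 0.6])
    )
    with pytest.raises(ValueError):
        ib.pool_correlations([])
    with pytest.raises(ValueError):
        ib.pool_correlations([0.5, 1.0])


def _noise_free_cohort(profiles, seed):
    """Simulate noise-free observers with bin-constant bias profiles, so a
    split-half at bin width 3 reproduces each profile exactly in both halves."""
    continuum = ib.build_continuum(3, 48)
    rng = np.random.default_rng(seed)
    frames = []
    for oid, profile in profiles.items():
        prof = ib.ObserverProfile(oid, "radiologist", profile)
        frames.append(
            ib.simulate_matching_session(prof, np.zeros(147), continuum, 300, rng)
        )
    return matching_errors(pd.concat(frames, ignore_index=True), continuum, 3)


def test_bootstrap_within_noise_free_observers_reach_unity():
    rng = np.random.default_rng(30)
    e = _noise_free_cohort(
        {f"R{i:02d}": np.repeat(rng.normal(0, 6, 49).round(), 3) for i in range(3)},
        seed=3,
    )
    res = ib.bootstrap_within(e, "radiologist", 49, n_iter=50, seed=1)
    assert res.mean_r == pytest.approx(1.0, abs=1e-6)
    assert res.ci_low <= res.mean_r <= res.ci_high
    assert set(res.per_observer_r) == {"R00", "R01", "R02"}


def test_bootstrap_between_shared_only_reaches_unity():
    rng = np.random.default_rng(31)
    common = np.repeat(rng.normal(0, 6, 49).round(), 3)
    e = _noise_free_cohort({f"R{i:02d}": common for i in range(3)}, seed=4)
    res = ib.bootstrap_between(e, "radiologist", 49, n_iter=50, seed=1)
    assert res.mean_r == pytest.approx(1.0, abs=1e-6)


def test_bootstrap_between_independent_profiles_near_zero():
    cfg = ib.MatchingCohortConfig(
        n_radiologists=6, n_untrained=2, bias_sd=6.0, shared_bias_sd=0.0,
        noise_sd=3.0, lapse_rate=0.0,
    )
    ds = ib.generate_matching_cohort(cfg, 5)
    e = matching_errors(ds.trials, ds.continuum, 3)
    res = ib.bootstrap_between(e, "radiologist", 49, n_iter=200, seed=1)
    assert abs(res.mean_r) < 0.15


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_within_exceeds_between_with_idiosyncratic_bias(seed):
    cfg = ib.MatchingCohortConfig(
        n_radiologists=6, n_untrained=2, bias_sd=5.0, shared_bias_sd=4.0,
        noise_sd=8.0, lapse_rate=0.0,
    )
    ds = ib.generate_matching_cohort(cfg, 100 + seed)
    e = matching_errors(ds.trials, ds.continuum, 3)
    w = ib.bootstrap_within(e, "radiologist", 49, n_iter=100, seed=seed)
    b = ib.bootstrap_between(e, "radiologist", 49, n_iter=100, seed=seed)
    assert w.mean_r > b.mean_r


def test_noise_does_not_increase_within_consistency():
    """Trial noise only attenuates the within-observer correlation."""
    means = []
    for noise in (4.0, 14.0):
        rs = []
        for rep in range(3):
            cfg = ib.MatchingCohortConfig(
                n_radiologists=6, n_untrained=2, bias_sd=5.0,
                shared_bias_sd=4.0, noise_sd=noise, lapse_rate=0.0,
            )
            ds = ib.generate_matching_cohort(cfg, 200 + rep)
            e = matching_errors(ds.trials, ds.continuum, 3)
            rs.append(ib.bootstrap_within(e, "radiologist", 49, 60, rep).mean_r)
        means.append(np.mean(rs))
    assert means[1] < means[0]


def test_test_retest_within_extremes(small_rating_cohort):
    e = rating_errors(small_rating_cohort.trials)
    oid = "R00"
    paired = cons.paired_phase_errors(e[e["observer_id"] == oid])[oid]
    # identical phases correlate at 1 by construction
    fake = e.copy()
    fake.loc[fake["phase"] == "retest", "error"] = np.nan
    init = paired["initial"]
    df = pd.DataFrame(
        {
            "observer_id": oid,
            "group": "radiologist",
            "image_id": list(init.index) * 2,
            "phase": ["initial"] * len(init) + ["retest"] * len(init),
            "error": list(init) * 2,
        }
    )
    assert ib.test_retest_within(df, oid) == pytest.approx(1.0)


def test_test_retest_pure_noise_near_zero():
    cfg = ib.RatingCohortConfig(
        n_radiologists=10, n_untrained=2, bias_sd=0.0, shared_bias_sd=0.0,
        noise_sd=1.5, discriminability=0.3,
    )
    ds = ib.generate_rating_cohort(cfg, 6)
    e = rating_errors(ds.trials)
    rs = [ib.test_retest_within(e, f"R{i:02d}") for i in range(10)]
    assert abs(np.mean(rs)) < 0.12


def test_bootstrap_observers_tracks_plugin_estimate(small_rating_cohort):
    e = rating_errors(small_rating_cohort.trials)
    res = ib.bootstrap_observers(e, "radiologist", "within", n_iter=1000, seed=2)
    plug_in = cons._pool(
        np.array([ib.test_retest_within(e, f"R{i:02d}") for i in range(4)])
    )
    assert res.mean_r == pytest.approx(plug_in, abs=0.02)
    assert res.ci_low <= res.mean_r <= res.ci_high


def test_bootstrap_observers_between_mode(small_rating_cohort):
    e = rating_errors(small_rating_cohort.trials)
    res = ib.bootstrap_observers(e, "radiologist", "between", n_iter=300, seed=3)
    assert -1 <= res.ci_low <= res.mean_r <= res.ci_high <= 1
    with pytest.raises(ValueError):
        ib.bootstrap_observers(e, "radiologist", "sideways")
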