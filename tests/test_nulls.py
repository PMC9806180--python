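"""Permutation nulls: circular shift (matching) and label shuffle (rating)."""

import numpy as np
import pandas as pd
import pytest

import idiobias as ib
from idiobias.errors import ErrorProfile, matching_errors, rating_errors
from idiobias.nulls import NullDistribution


def _profile(keys, values):
    return ErrorProfile(
        observer_id="o",
        group="radiologist",
        errors=pd.Series(values, index=keys, dtype=float),
        n_trials=pd.Series(1, index=keys),
    )


def test_shift_profile_relabels_keys():
    p = _profile([0, 1, 2], [1.0, 2.0, 3.0])
    shifted = ib.shift_profile(p, 6, n_keys=49)
    assert list(shifted.errors.index) == [6, 7, 8]
    assert sorted(shifted.errors) == [1.0, 2.0, 3.0]


def test_shift_profile_inverse_recovers_identity():
    p = _profile([0, 5, 48], [1.0, -2.0, 3.0])
    round_trip = ib.shift_profile(ib.shift_profile(p, 7, 49), 42, 49)
    pd.testing.assert_series_equal(
        round_trip.errors.sort_index(), p.errors.sort_index()
    )


def test_shift_profile_rejects_degenerate_shifts():
    p = _profile([0, 1, 2], [1.0, 2.0, 3.0])
    for bad in (0, 49, -3):
        with pytest.raises(ValueError):
            ib.shift_profile(p, bad, n_keys=49)


def test_shift_profile_preserves_value_multiset_dense():
    rng = np.random.default_rng(0)
    dense = rng.normal(size=49)
    for shift in (1, 13, 48):
        shifted = ib.shift_profile(dense, shift)
        assert sorted(shifted) == sorted(dense)


def _zero_bias_cohort(seed, n_obs=6):
    cfg = ib.MatchingCohortConfig(
        n_radiologists=n_obs, n_untrained=2, bias_sd=0.0, shared_bias_sd=0.0,
        noise_sd=12.0, lapse_rate=0.0,
    )
    ds = ib.generate_matching_cohort(cfg, seed)
    return matching_errors(ds.trials, ds.continuum, 3)


def test_null_within_matching_centered_at_zero():
    e = _zero_bias_cohort(1)
    null = ib.null_within_matching(e, "radiologist", 49, n_iter=3000, seed=2)
    assert abs(null.mean) < 0.03
    assert null.upper_97_5 > 0
    assert len(null.samples) == 3000


def test_null_between_matching_centered_and_exceeded_by_shared_bias():
    e = _zero_bias_cohort(3)
    null = ib.null_between_matching(e, "radiologist", 49, n_iter=2000, seed=4)
    assert abs(null.mean) < 0.04

    cfg = ib.MatchingCohortConfig(
        n_radiologists=3, n_untrained=2, bias_sd=0.0, shared_bias_sd=6.0,
        noise_sd=0.0, lapse_rate=0.0,
    )
    ds = ib.generate_matching_cohort(cfg, 5)
    e2 = matching_errors(ds.trials, ds.continuum, 3)
    observed = ib.bootstrap_between(e2, "radiologist", 49, 30, 1).mean_r
    null2 = ib.null_between_matching(e2, "radiologist", 49, n_iter=500, seed=6)
    assert observed > null2.upper_97_5


def test_noise_free_biased_observer_beats_within_null():
    continuum = ib.build_continuum(3, 48)
    rng = np.random.default_rng(40)
    frames = []
    for i in range(3):
        profile = np.repeat(rng.normal(0, 6, 49).round(), 3)
        prof = ib.ObserverProfile(f"R{i:02d}", "radiologist", profile)
        frames.append(
            ib.simulate_matching_session(prof, np.zeros(147), continuum, 300, rng)
        )
    e = matching_errors(pd.concat(frames, ignore_index=True), continuum, 3)
    observed = ib.bootstrap_within(e, "radiologist", 49, 30, 1).mean_r
    null = ib.null_within_matching(e, "radiologist", 49, n_iter=500, seed=8)
    assert observed == pytest.approx(1.0, abs=1e-6)
    assert observed > null.upper_97_5


def test_shift_null_wider_than_iid_shuffle_for_smooth_profiles():
    """Circular shifting preserves profile autocorrelation, so for smooth
    bias profiles the shift null is wider than a naive i.i.d. shuffle null —
    the reason shifting is the right chance model here."""
    rng = np.random.default_rng(9)
    shift_rs, shuffle_rs = [], []
    for _ in range(400):
        a = ib.make_bias_profile(49, 8.0, 1.0, rng) + rng.normal(0, 0.3, 49)
        b = ib.make_bias_profile(49, 8.0, 1.0, rng) + rng.normal(0, 0.3, 49)
        s = rng.integers(1, 49)
        shift_rs.append(np.corrcoef(np.roll(a, s), a * 0 + b)[0, 1])
        shuffle_rs.append(np.corrcoef(rng.permutation(a), b)[0, 1])
    assert np.std(shift_rs) > 1.3 * np.std(shuffle_rs)


def test_null_rating_centered_and_beaten_by_biased_observer():
    cfg = ib.RatingCohortConfig(n_radiologists=4, n_untrained=2)
    ds = ib.generate_rating_cohort(cfg, 10)
    e = rating_errors(ds.trials)
    null = ib.null_rating(e, "radiologist", "within", n_iter=2000, seed=11)
    assert abs(null.mean) < 0.03
    assert null.n_degenerate_redraws == 0

    strong = ib.RatingCohortConfig(
        n_radiologists=3, n_untrained=2, bias_sd=3.0, shared_bias_sd=0.0,
        noise_sd=0.0,
    )
    ds2 = ib.generate_rating_cohort(strong, 12)
    e2 = rating_errors(ds2.trials)
    observed = ib.bootstrap_observers(e2, "radiologist", "within", 30, 1).mean_r
    null2 = ib.null_rating(e2, "radiologist", "within", n_iter=500, seed=13)
    assert observed == pytest.approx(1.0, abs=1e-6)
    assert observed > null2.upper_97_5


def test_null_rating_all_constant_raises():
    rows = []
    for oid in ("A", "B"):
        for phase in ("initial", "retest"):
            for img in range(6):
                rows.append((oid, "radiologist", img, phase, 2.0))
    e = pd.DataFrame(rows, columns=["observer_id", "group", "image_id", "phase", "error"])
    with pytest.raises(ValueError):
        ib.null_rating(e, "radiologist", "within", n_iter=5, seed=1, max_redraws=5)


def test_null_pvalue_properties():
    null = NullDistribution("within", "matching", np.linspace(-0.5, 0.5, 999), 999)
    assert ib.null_pvalue(-0.9, null) == pytest.approx(1.0)
    assert ib.null_pvalue(0.0, null) == pytest.approx(0.5, abs=0.01)
    assert ib.null_pvalue(0.9, null) == pytest.approx(1 / 1000)
    assert ib.null_pvalue(0.9, null) < 0.001 + 1e-9
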