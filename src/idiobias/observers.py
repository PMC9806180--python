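"""Synthetic observers for the two task designs.

Neither task's human data are public, so validation of the analysis chain
rests on simulated observers whose generative parameters are known exactly.
Two designs are emulated:

* **matching** — continuous report on a circular morph continuum.  Each
  observer carries a smooth, stimulus-specific signed-bias profile (a
  band-limited random Fourier series on the loop), a weight on a bias
  profile shared by the whole group, Gaussian trial noise, and a lapse
  rate (uniform random response).
* **rating** — realness ratings of real vs. GAN-generated lesion images on
  a 0-10 scale.  Each observer carries an image-specific rating-bias
  profile (identical in the initial and retest phases), a shared group
  profile, a discriminability parameter pulling latent ratings toward the
  scale midpoint, Gaussian noise, and an affine response propensity
  (gain/offset) applied before clipping to the scale.

The generator parameters are constructs of this package for parameter
recovery testing; they are not estimates of any published cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .continuum import StimulusContinuum, build_continuum

__all__ = [
    "ObserverProfile",
    "MatchingCohortConfig",
    "RatingCohortConfig",
    "CohortDataset",
    "make_bias_profile",
    "simulate_matching_session",
    "simulate_rating_session",
    "generate_matching_cohort",
    "generate_rating_cohort",
    "generate_cohort",
]

Group = Literal["radiologist", "untrained"]

MATCHING_COLUMNS = [
    "observer_id",
    "group",
    "trial_index",
    "target_index",
    "response_index",
]
RATING_COLUMNS = [
    "observer_id",
    "group",
    "trial_index",
    "image_id",
    "truth_label",
    "phase",
    "raw_rating",
]


@dataclass
class ObserverProfile:
    """Generative parameters of one synthetic observer.

    ``bias_profile`` holds the expected signed error per stimulus (matching
    design, morph units) or the expected rating deviation per image (rating
    design, rating units).  ``shared_weight`` scales a group-common bias
    profile added on top.  ``propensity_gain``/``propensity_offset`` apply
    only to the rating design.
    """

    observer_id: str
    group: str
    bias_profile: np.ndarray
    shared_weight: float = 1.0
    noise_sd: float = 0.0
    lapse_rate: float = 0.0
    propensity_gain: float = 1.0
    propensity_offset: float = 0.0

    def __post_init__(self) -> None:
        self.bias_profile = np.asarray(self.bias_profile, dtype=float)
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["bias_profile"] = [float(v) for v in self.bias_profile]
        return d


def make_bias_profile(
    n_points: int,
    smoothness: float,
    bias_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a smooth zero-mean periodic bias profile on the circular index set.

    The profile is a truncated random Fourier series: harmonics ``k`` with
    wavelength ``n_points / k >= smoothness`` receive independent standard
    normal sine and cosine coefficients, scaled so the profile's expected
    per-point variance is ``bias_sd**2``.  ``smoothness`` is the correlation
    length in stimulus units; larger values give slower-varying profiles.
    Smoothness is what makes a circular-shift null genuinely different from
    an i.i.d. shuffle null downstream.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if bias_sd < 0:
        raise ValueError("bias_sd must be >= 0")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    k_max = max(1, int(n_points / smoothness))
    k_max = max(1, min(k_max, (n_points - 1) // 2))  # stay below Nyquist
    ks = np.arange(1, k_max + 1)
    a = rng.standard_normal(k_max)
    b = rng.standard_normal(k_max)
    theta = 2.0 * np.pi * np.outer(np.arange(n_points), ks) / n_points
    profile = np.cos(theta) @ a + np.sin(theta) @ b
    # each harmonic contributes variance (a_k^2 + b_k^2)/2 averaged over the
    # loop; with unit-variance coefficients the profile variance is k_max.
    profile *= bias_sd / np.sqrt(k_max)
    return profile


def simulate_matching_session(
    profile: ObserverProfile,
    shared_profile: np.ndarray,
    continuum: StimulusContinuum,
    n_trials: int,
    rng: np.random.Generator,
    balanced_targets: bool = False,
) -> pd.DataFrame:
    """Simulate one observer's continuous-report matching session.

    Per trial: a uniform random target index; the response is the target
    plus the observer's bias at that target, the weighted shared bias, and
    Gaussian noise, rounded and wrapped to the loop.  With probability
    ``lapse_rate`` the response is instead uniform on the continuum.

    ``balanced_targets`` presents every stimulus equally often (in random
    order) instead of sampling targets uniformly; ``n_trials`` must then be
    a multiple of the continuum size.  Useful for calibration studies where
    equal per-stimulus trial counts are wanted.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n = continuum.n_total
    if len(profile.bias_profile) != n:
        raise ValueError("bias_profile length must equal continuum size")
    shared = np.asarray(shared_profile, dtype=float)
    if len(shared) != n:
        raise ValueError("shared_profile length must equal continuum size")

    if balanced_targets:
        if n_trials % n:
            raise ValueError("balanced design needs n_trials divisible by n_total")
        targets = rng.permutation(np.repeat(np.arange(n), n_trials // n))
    else:
        targets = rng.integers(0, n, size=n_trials)
    shift = (
        profile.bias_profile[targets]
        + profile.shared_weight * shared[targets]
        + rng.normal(0.0, profile.noise_sd, size=n_trials)
    )
    responses = (targets + np.rint(shift).astype(np.int64)) % n
    lapses = rng.random(n_trials) < profile.lapse_rate
    if lapses.any():
        responses[lapses] = rng.integers(0, n, size=int(lapses.sum()))
    return pd.DataFrame(
        {
            "observer_id": profile.observer_id,
            "group": profile.group,
            "trial_index": np.arange(n_trials),
            "target_index": targets,
            "response_index": responses,
        }
    )


def draw_retest_set(
    truth_labels: np.ndarray, n_repeats: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a balanced retest image set: n_repeats/2 real + n_repeats/2 gan."""
    truth_labels = np.asarray(truth_labels)
    k = n_repeats // 2
    ids = np.concatenate(
        [
            rng.choice(np.flatnonzero(truth_labels == "real"), size=k, replace=False),
            rng.choice(np.flatnonzero(truth_labels == "gan"), size=k, replace=False),
        ]
    )
    rng.shuffle(ids)
    return ids


def simulate_rating_session(
    profile: ObserverProfile,
    truth_labels: np.ndarray,
    n_repeats: int,
    rng: np.random.Generator,
    shared_profile: np.ndarray | None = None,
    discriminability: float = 0.0,
    noise_sd: float | None = None,
    retest_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one observer's realness-rating session.

    ``truth_labels`` is an array of "real"/"gan" strings, one per image and
    balanced between the two classes.  The latent rating of image ``m`` is
    the ground-truth value (10 real, 0 gan) pulled toward the scale midpoint
    by ``discriminability`` in [0, 1], plus the observer's image bias
    (identical whenever the image repeats), the weighted shared bias, and
    Gaussian trial noise; the observed rating is the latent rating passed
    through the affine propensity and clipped to [0, 10].

    All images appear once in the initial phase; ``n_repeats`` of them
    (balanced real/gan) appear once more as the retest phase, giving
    ``n_images + n_repeats`` trials.  The retest set is drawn here unless
    ``retest_ids`` is given — a cohort normally fixes one retest set for
    all its observers, as the test-retest design prescribes.
    """
    truth_labels = np.asarray(truth_labels)
    n_images = len(truth_labels)
    if len(profile.bias_profile) != n_images:
        raise ValueError("bias_profile length must equal number of images")
    real_ids = np.flatnonzero(truth_labels == "real")
    gan_ids = np.flatnonzero(truth_labels == "gan")
    if len(real_ids) != len(gan_ids):
        raise ValueError("image set must be half real / half gan")
    if n_repeats > n_images:
        raise ValueError("n_repeats cannot exceed the number of images")
    if n_repeats % 2:
        raise ValueError("n_repeats must be even to balance real/gan retests")

    shared = (
        np.zeros(n_images)
        if shared_profile is None
        else np.asarray(shared_profile, dtype=float)
    )
    sd = profile.noise_sd if noise_sd is None else noise_sd

    if retest_ids is None:
        retest_ids = draw_retest_set(truth_labels, n_repeats, rng)
    else:
        retest_ids = np.asarray(retest_ids)
        if len(retest_ids) != n_repeats:
            raise ValueError("retest_ids length must equal n_repeats")

    image_ids = np.concatenate([np.arange(n_images), retest_ids])
    phases = np.array(["initial"] * n_images + ["retest"] * n_repeats)
    truth = truth_labels[image_ids]
    truth_value = np.where(truth == "real", 10.0, 0.0)
    latent = (
        5.0
        + discriminability * (truth_value - 5.0)
        + profile.bias_profile[image_ids]
        + profile.shared_weight * shared[image_ids]
        + rng.normal(0.0, sd, size=len(image_ids))
    )
    observed = np.clip(
        profile.propensity_gain * latent + profile.propensity_offset, 0.0, 10.0
    )
    return pd.DataFrame(
        {
            "observer_id": profile.observer_id,
            "group": profile.group,
            "trial_index": np.arange(len(image_ids)),
            "image_id": image_ids,
            "truth_label": truth,
            "phase": phases,
            "raw_rating": observed,
        }
    )


# --------------------------------------------------------------------------
# cohort generation


@dataclass
class MatchingCohortConfig:
    """Study conditions for a simulated matching cohort.

    Defaults mirror the analyzed design: 13 radiologists and 11 untrained
    observers, 255 trials each, on a 147-step loop (3 prototypes, 48 morphs
    per pair).  Bias magnitudes are this package's choice of a realistic
    regime: idiosyncratic bias SD 5 and shared bias SD 4 morph units against
    trial noise SD 12 put split-half consistency in the range typically seen
    in continuous-report data.
    """

    n_radiologists: int = 13
    n_untrained: int = 11
    n_trials: int = 255
    n_prototypes: int = 3
    n_morphs_per_pair: int = 48
    bias_sd: float = 5.0
    shared_bias_sd: float = 4.0
    shared_weight: float = 1.0
    noise_sd: float = 12.0
    lapse_rate: float = 0.02
    smoothness: float = 15.0
    balanced_targets: bool = False


@dataclass
class RatingCohortConfig:
    """Study conditions for a simulated rating cohort.

    Defaults mirror the analyzed design: 7 radiologists and 5 untrained
    observers, 100 images (50 real + 50 GAN), 40 balanced retest
    presentations.  A low discriminability (0.08) keeps d' in the
    near-chance regime characteristic of realistic GAN images; bias SD 2 and
    shared SD 1 rating units against noise SD 1.5 give a clearly positive
    test-retest correlation.  Per-observer propensity gain/offset are drawn
    uniformly from the stated ranges.
    """

    n_radiologists: int = 7
    n_untrained: int = 5
    n_images: int = 100
    n_repeats: int = 40
    bias_sd: float = 2.0
    shared_bias_sd: float = 1.0
    shared_weight: float = 1.0
    noise_sd: float = 1.5
    discriminability: float = 0.08
    gain_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-1.0, 1.0)
    smoothness: float = 10.0


@dataclass
class CohortDataset:
    """A simulated two-group dataset plus its ground truth.

    ``trials`` is a tidy trial table (one row per trial); ``profiles`` maps
    observer id to the generating :class:`ObserverProfile`;
    ``shared_profiles`` maps group name to the group-common bias profile.
    """

    experiment: str
    trials: pd.DataFrame
    profiles: dict[str, ObserverProfile]
    shared_profiles: dict[str, np.ndarray]
    seed: int
    continuum: StimulusContinuum | None = None
    truth_labels: np.ndarray | None = None

    def write(self, trials_path: str | Path, profiles_path: str | Path | None = None):
        """Write the trial table as CSV and the ground truth as JSON."""
        self.trials.to_csv(trials_path, index=False)
        if profiles_path is not None:
            payload = {
                "experiment": self.experiment,
                "seed": self.seed,
                "profiles": {k: p.to_jsonable() for k, p in self.profiles.items()},
                "shared_profiles": {
                    g: [float(v) for v in prof]
                    for g, prof in self.shared_profiles.items()
                },
            }
            Path(profiles_path).write_text(json.dumps(payload, indent=1))


def _observer_ids(config) -> list[tuple[str, str]]:
    ids = [(f"R{i:02d}", "radiologist") for i in range(config.n_radiologists)]
    ids += [(f"U{i:02d}", "untrained") for i in range(config.n_untrained)]
    return ids


def generate_matching_cohort(
    config: MatchingCohortConfig, seed: int
) -> CohortDataset:
    """Simulate a full two-group matching cohort, reproducible from seed."""
    rng = np.random.default_rng(seed)
    continuum = build_continuum(config.n_prototypes, config.n_morphs_per_pair)
    n = continuum.n_total
    shared = {
        g: make_bias_profile(n, config.smoothness, config.shared_bias_sd, rng)
        for g in ("radiologist", "untrained")
    }
    profiles: dict[str, ObserverProfile] = {}
    frames = []
    for oid, group in _observer_ids(config):
        prof = ObserverProfile(
            observer_id=oid,
            group=group,
            bias_profile=make_bias_profile(n, config.smoothness, config.bias_sd, rng),
            shared_weight=config.shared_weight,
            noise_sd=config.noise_sd,
            lapse_rate=config.lapse_rate,
        )
        profiles[oid] = prof
        frames.append(
            simulate_matching_session(
                prof,
                shared[group],
                continuum,
                config.n_trials,
                rng,
                balanced_targets=config.balanced_targets,
            )
        )
    return CohortDataset(
        experiment="matching",
        trials=pd.concat(frames, ignore_index=True),
        profiles=profiles,
        shared_profiles=shared,
        seed=seed,
        continuum=continuum,
    )


def generate_rating_cohort(config: RatingCohortConfig, seed: int) -> CohortDataset:
    """Simulate a full two-group rating cohort, reproducible from seed."""
    rng = np.random.default_rng(seed)
    m = config.n_images
    truth_labels = np.array(["real"] * (m // 2) + ["gan"] * (m - m // 2))
    rng.shuffle(truth_labels)
    shared = {
        g: make_bias_profile(m, config.smoothness, config.shared_bias_sd, rng)
        for g in ("radiologist", "untrained")
    }
    retest_ids = draw_retest_set(truth_labels, config.n_repeats, rng)
    profiles: dict[str, ObserverProfile] = {}
    frames = []
    for oid, group in _observer_ids(config):
        prof = ObserverProfile(
            observer_id=oid,
            group=group,
            bias_profile=make_bias_profile(m, config.smoothness, config.bias_sd, rng),
            shared_weight=config.shared_weight,
            noise_sd=config.noise_sd,
            propensity_gain=rng.uniform(*config.gain_range),
            propensity_offset=rng.uniform(*config.offset_range),
        )
        profiles[oid] = prof
        frames.append(
            simulate_rating_session(
                prof,
                truth_labels,
                config.n_repeats,
                rng,
                shared_profile=shared[group],
                discriminability=config.discriminability,
                retest_ids=retest_ids,
            )
        )
    return CohortDataset(
        experiment="rating",
        trials=pd.concat(frames, ignore_index=True),
        profiles=profiles,
        shared_profiles=shared,
        seed=seed,
        truth_labels=truth_labels,
    )


def generate_cohort(config, seed: int) -> CohortDataset:
    """Dispatch on config type to the matching or rating generator."""
    if isinstance(config, MatchingCohortConfig):
        return generate_matching_cohort(config, seed)
    if isinstance(config, RatingCohortConfig):
        return generate_rating_cohort(config, seed)
    raise TypeError(f"unknown cohort config type: {type(config)!r}")
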