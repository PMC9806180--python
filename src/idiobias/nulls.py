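"""Chance-level null distributions for consistency statistics.

Split-half and test-retest correlations need a chance reference that
respects the data's structure.  A naive i.i.d. shuffle would break the
similarity between neighbouring stimuli and understate the null variance
when error profiles are smooth; the matching-design null therefore
*circularly shifts* the stimulus labels of one split half before
correlating (a Monte Carlo permutation that destroys alignment but keeps
each half's internal autocorrelation).  The rating-design null shuffles
image labels of the initial and retest error vectors independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consistency import (
    _group_engines,
    _masked_corr_matrix,
    _phase_matrices,
    _pool,
    _split_all,
)
from .errors import ErrorProfile

__all__ = [
    "NullDistribution",
    "shift_profile",
    "null_within_matching",
    "null_between_matching",
    "null_rating",
    "null_pvalue",
]


@dataclass
class NullDistribution:
    """Samples of a pooled correlation under a permutation null.

    ``upper_97_5`` is the empirical 97.5th percentile, the bound drawn as
    the chance-level line in summary figures.  ``n_degenerate_redraws``
    counts iterations that had to be redrawn because every correlation in
    the pool was undefined (constant vectors).
    """

    mode: str
    experiment: str
    samples: np.ndarray = field(repr=False)
    n_iterations: int
    n_degenerate_redraws: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != self.n_iterations:
            raise ValueError("samples length must equal n_iterations")

    @property
    def upper_97_5(self) -> float:
        return float(np.percentile(self.samples, 97.5))

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    def to_jsonable(self) -> dict:
        return {
            "mode": self.mode,
            "experiment": self.experiment,
            "n_iterations": self.n_iterations,
            "mean": self.mean,
            "upper_97_5": self.upper_97_5,
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }


def shift_profile(profile, shift: int, n_keys: int | None = None):
    """Circularly re-label an error profile's keys: key k -> (k + shift) mod n.

    ``shift`` must lie in [1, n_keys - 1]; a zero shift would reproduce the
    true alignment and a full-cycle shift is no permutation at all.  Values
    are untouched, so the profile's value multiset is preserved exactly.
    Accepts an :class:`ErrorProfile` (sparse keys) or a dense array with
    NaN for missing keys.
    """
    if isinstance(profile, ErrorProfile):
        if n_keys is None:
            raise ValueError("n_keys is required for sparse profiles")
        if not (1 <= shift <= n_keys - 1):
            raise ValueError(f"shift must be in [1, {n_keys - 1}]")
        new_index = (profile.errors.index.to_numpy() + shift) % n_keys
        return ErrorProfile(
            observer_id=profile.observer_id,
            group=profile.group,
            errors=pd.Series(profile.errors.to_numpy(), index=new_index).sort_index(),
            n_trials=pd.Series(
                profile.n_trials.to_numpy(), index=new_index
            ).sort_index(),
        )
    arr = np.asarray(profile, dtype=float)
    n = len(arr) if n_keys is None else n_keys
    if not (1 <= shift <= n - 1):
        raise ValueError(f"shift must be in [1, {n - 1}]")
    return np.roll(arr, shift)


def _roll_rows(A: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Roll each row of ``A`` by its own shift (vectorized)."""
    n = A.shape[1]
    cols = (np.arange(n)[None, :] - shifts[:, None]) % n
    return A[np.arange(A.shape[0])[:, None], cols]


def null_within_matching(
    errors: pd.DataFrame,
    group: str,
    n_keys: int,
    n_iter: int = 10_000,
    seed: int = 0,
    key: str = "stim_bin",
) -> NullDistribution:
    """Shift-permutation null for within-observer split-half consistency.

    Per iteration, per observer: re-split, circularly shift one half's bin
    labels by an observer-specific uniform shift in [1, n_keys - 1], and
    correlate with the unchanged half; pool across observers on the Fisher
    z scale into one null sample.
    """
    ids, engines = _group_engines(errors, group, n_keys, key)
    if len(ids) < 2:
        raise ValueError("need >= 2 observers")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter)
    for it in range(n_iter):
        A, B = _split_all(engines, rng)
        shifts = rng.integers(1, n_keys, size=len(ids))
        r = np.einsum("ii->i", _masked_corr_matrix(_roll_rows(A, shifts), B))
        samples[it] = _pool(r.copy())
    return NullDistribution("within", "matching", samples, n_iter)


def null_between_matching(
    errors: pd.DataFrame,
    group: str,
    n_keys: int,
    n_iter: int = 10_000,
    seed: int = 0,
    key: str = "stim_bin",
) -> NullDistribution:
    """Shift-permutation null for between-observer consistency: the shifted
    half of each observer is correlated with the unchanged half of every
    other observer; pairwise correlations pooled per iteration."""
    ids, engines = _group_engines(errors, group, n_keys, key)
    if len(ids) < 2:
        raise ValueError("need >= 2 observers")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(ids), k=1)
    samples = np.empty(n_iter)
    for it in range(n_iter):
        A, B = _split_all(engines, rng)
        shifts = rng.integers(1, n_keys, size=len(ids))
        rmat = _masked_corr_matrix(_roll_rows(A, shifts), B)
        samples[it] = _pool(rmat[iu])
    return NullDistribution("between", "matching", samples, n_iter)


def null_rating(
    errors: pd.DataFrame,
    group: str,
    mode: str,
    n_iter: int = 10_000,
    seed: int = 0,
    max_redraws: int = 100,
) -> NullDistribution:
    """Label-shuffle null for test-retest consistency (rating design).

    Per iteration the image labels of every observer's initial-phase and
    retest-phase error vectors are permuted independently; ``within`` mode
    correlates each observer's shuffled initial with their own shuffled
    retest errors, ``between`` mode correlates shuffled initial errors of
    one observer with shuffled retest errors of every other.  Iterations in
    which every correlation in the pool is undefined (constant vectors) are
    redrawn and counted.
    """
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    ids, init, retest = _phase_matrices(errors, group)
    n = len(ids)
    if mode == "between" and n < 2:
        raise ValueError("need >= 2 observers for a between-observer null")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    m = init.shape[1]
    samples = np.empty(n_iter)
    n_redraws = 0
    for it in range(n_iter):
        for _attempt in range(max_redraws):
            ip = np.take_along_axis(
                init, np.argsort(rng.random((n, m)), axis=1), axis=1
            )
            rp = np.take_along_axis(
                retest, np.argsort(rng.random((n, m)), axis=1), axis=1
            )
            rmat = _masked_corr_matrix(ip, rp)
            pool = (
                np.einsum("ii->i", rmat).copy()
                if mode == "within"
                else np.concatenate([rmat[iu], rmat.T[iu]])
            )
            value = _pool(pool)
            if np.isfinite(value):
                break
            n_redraws += 1
        else:
            raise ValueError(
                "every correlation degenerate (constant error vectors); "
                f"gave up after {max_redraws} redraws"
            )
        samples[it] = value
    return NullDistribution(mode, "rating", samples, n_iter, n_redraws)


def null_pvalue(observed: float, null: NullDistribution) -> float:
    """One-sided permutation p-value with the plus-one correction:
    ``(#{null >= observed} + 1) / (n_iterations + 1)``."""
    if len(null.samples) == 0:
        raise ValueError("empty null distribution")
    exceed = int(np.sum(null.samples >= observed))
    return (exceed + 1) / (null.n_iterations + 1)
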