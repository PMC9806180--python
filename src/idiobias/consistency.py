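"""Within- and between-observer consistency of error profiles.

The signature of an idiosyncratic perceptual bias is that an observer's
per-stimulus error profile correlates with itself across independent data
halves (split-half, matching design) or across repeated presentations
(test-retest, rating design), while correlating less with other observers'
profiles.  Correlations are Pearson over profile keys, averaged through the
Fisher z transform, with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ErrorProfile

__all__ = [
    "ConsistencyResult",
    "split_half",
    "profile_correlation",
    "fisher_z",
    "inverse_fisher_z",
    "pool_correlations",
    "bootstrap_within",
    "bootstrap_between",
    "test_retest_within",
    "paired_phase_errors",
    "bootstrap_observers",
]

#: minimum number of shared keys for a profile correlation
MIN_SHARED_KEYS = 3

_ATANH_CLIP = 1.0 - 1e-15  # keeps |r|=1 finite-but-saturating inside loops


# --------------------------------------------------------------------------
# result container


@dataclass
class ConsistencyResult:
    """Pooled correlation with bootstrap CI.

    ``samples`` holds the per-iteration pooled correlations (the bootstrap
    distribution); ``mean_r`` is their mean and ``ci_low``/``ci_high`` the
    2.5th/97.5th percentiles.  ``per_observer_r`` (within mode) maps
    observer id to that observer's iteration-averaged correlation.
    """

    mode: str
    group: str
    mean_r: float
    ci_low: float
    ci_high: float
    n_iterations: int
    per_observer_r: dict[str, float] | None = None
    samples: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (
            -1.0 <= self.ci_low <= self.mean_r + 1e-12
            and self.mean_r - 1e-12 <= self.ci_high <= 1.0
        ):
            raise ValueError("require -1 <= ci_low <= mean_r <= ci_high <= 1")

    def to_jsonable(self) -> dict:
        d = {
            "mode": self.mode,
            "group": self.group,
            "mean_r": self.mean_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iterations": self.n_iterations,
        }
        if self.per_observer_r is not None:
            d["per_observer_r"] = self.per_observer_r
        return d


# --------------------------------------------------------------------------
# Fisher transform and pooling


def fisher_z(r: float) -> float:
    """Fisher z transform, atanh(r); requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    """Inverse Fisher transform, tanh(z)."""
    return float(np.tanh(z))


def pool_correlations(rs) -> float:
    """Average correlations on the Fisher z scale: tanh(mean(atanh(r)))."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("cannot pool an empty list of correlations")
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("all |r| must be < 1 to pool on the z scale")
    return float(np.tanh(np.mean(np.arctanh(rs))))


def _pool(rs: np.ndarray) -> float:
    """Tolerant Fisher pooling used inside resampling loops: NaN entries
    (undefined correlations) are dropped; |r| = 1 saturates instead of
    raising.  Returns NaN when nothing survives."""
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return np.nan
    return float(np.tanh(np.mean(np.arctanh(np.clip(rs, -_ATANH_CLIP, _ATANH_CLIP)))))


# --------------------------------------------------------------------------
# profile correlation


def _series_of(profile) -> pd.Series:
    if isinstance(profile, ErrorProfile):
        return profile.errors
    return pd.Series(profile)


def profile_correlation(a, b) -> float:
    """Pearson correlation of two error profiles over their shared keys.

    Keys missing from either profile are dropped (pairwise complete).
    Raises if fewer than ``MIN_SHARED_KEYS`` keys remain or if either
    profile is constant over them.
    """
    sa, sb = _series_of(a), _series_of(b)
    joined = pd.concat([sa, sb], axis=1, join="inner").dropna()
    if len(joined) < MIN_SHARED_KEYS:
        raise ValueError(
            f"need >= {MIN_SHARED_KEYS} shared keys, got {len(joined)}"
        )
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an error profile")
    return float(np.corrcoef(x, y)[0, 1])


# --------------------------------------------------------------------------
# fast split engine (internal)


class _BinnedTrials:
    """One observer's trial errors grouped by key, ready for repeated
    random half-splits.

    Trials are pre-sorted by key; a split draws a random order within each
    key block and assigns the first ceil(k/2) or floor(k/2) trials (the
    extra trial going to a random half) to half 0.
    """

    def __init__(self, keys: np.ndarray, errors: np.ndarray, n_keys: int):
        keys = np.asarray(keys, dtype=np.int64)
        errors = np.asarray(errors, dtype=float)
        order = np.argsort(keys, kind="stable")
        self.keys_sorted = keys[order]
        self.errs_sorted = errors[order]
        self.counts = np.bincount(keys, minlength=n_keys)
        starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self.pos = np.arange(len(keys)) - np.repeat(starts, self.counts)
        self.total_sums = np.bincount(keys, weights=errors, minlength=n_keys)
        self.n_keys = n_keys
        self.n_trials = len(keys)

    def split_means(self, rng: np.random.Generator, with_counts: bool = False):
        """One random split; returns dense (mean0, mean1) arrays of length
        ``n_keys`` with NaN where a half received no trials.  With
        ``with_counts`` also returns the per-half trial counts."""
        u = rng.random(self.n_trials)
        order = np.argsort(self.keys_sorted + 0.5 * u)
        errs = self.errs_sorted[order]
        extra = rng.integers(0, 2, self.n_keys)
        n0 = self.counts // 2 + (self.counts % 2) * extra
        n1 = self.counts - n0
        in_half0 = self.pos < n0[self.keys_sorted]
        sum0 = np.bincount(
            self.keys_sorted[in_half0], weights=errs[in_half0], minlength=self.n_keys
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mean0 = np.where(n0 > 0, sum0 / n0, np.nan)
            mean1 = np.where(n1 > 0, (self.total_sums - sum0) / n1, np.nan)
        if with_counts:
            return mean0, mean1, n0, n1
        return mean0, mean1


def _group_engines(errors: pd.DataFrame, group: str, n_keys: int, key: str = "stim_bin"):
    sub = errors[errors["group"] == group]
    ids = sorted(sub["observer_id"].unique())
    if len(ids) == 0:
        raise ValueError(f"no observers in group {group!r}")
    engines = []
    for oid in ids:
        o = sub[sub["observer_id"] == oid]
        engines.append(_BinnedTrials(o[key].to_numpy(), o["error"].to_numpy(), n_keys))
    return ids, engines


def _masked_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlations between every row of ``A``
    and every row of ``B`` (NaN = missing).  Entry (i, j) correlates
    A[i] with B[j]; undefined entries (too few shared keys, zero variance)
    are NaN."""
    MA = np.isfinite(A)
    MB = np.isfinite(B)
    X = np.where(MA, A, 0.0)
    Y = np.where(MB, B, 0.0)
    ma = MA.astype(float)
    mb = MB.astype(float)
    n = ma @ mb.T
    sxy = X @ Y.T
    sx = X @ mb.T
    sy = ma @ Y.T
    sxx = (X * X) @ mb.T
    syy = ma @ (Y * Y).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < MIN_SHARED_KEYS)] = np.nan
    return r


def _split_all(engines, rng) -> tuple[np.ndarray, np.ndarray]:
    halves0, halves1 = [], []
    for eng in engines:
        m0, m1 = eng.split_means(rng)
        halves0.append(m0)
        halves1.append(m1)
    return np.asarray(halves0), np.asarray(halves1)


# --------------------------------------------------------------------------
# public operations — matching design (split-half)


def split_half(
    observer_errors: pd.DataFrame,
    n_keys: int,
    seed: int | np.random.Generator,
    key: str = "stim_bin",
) -> tuple[ErrorProfile, ErrorProfile]:
    """Randomly split one observer's trials into two near-equal halves per
    key and return the per-half mean-error profiles.

    Keys with a single trial contribute to only one half; the half is
    chosen at random.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    eng = _BinnedTrials(
        observer_errors[key].to_numpy(), observer_errors["error"].to_numpy(), n_keys
    )
    m0, m1, n0, n1 = eng.split_means(rng, with_counts=True)
    oid = str(observer_errors["observer_id"].iloc[0])
    grp = str(observer_errors["group"].iloc[0])
    profiles = []
    for m, counts in ((m0, n0), (m1, n1)):
        present = np.flatnonzero(np.isfinite(m))
        profiles.append(
            ErrorProfile(
                observer_id=oid,
                group=grp,
                errors=pd.Series(m[present], index=present),
                n_trials=pd.Series(counts[present], index=present),
            )
        )
    return profiles[0], profiles[1]


def bootstrap_within(
    errors: pd.DataFrame,
    group: str,
    n_keys: int,
    n_iter: int = 1000,
    seed: int = 0,
    key: str = "stim_bin",
) -> ConsistencyResult:
    """Bootstrap the within-observer split-half consistency of a group.

    Per iteration every observer is independently re-split, the two halves
    correlated, and the per-observer correlations pooled on the Fisher z
    scale into one sample.  Returns the sample mean, the 95% percentile
    interval, and each observer's iteration-averaged correlation.
    """
    ids, engines = _group_engines(errors, group, n_keys, key)
    if len(ids) < 2:
        raise ValueError("need >= 2 observers for group-level consistency")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter)
    per_obs = np.empty((n_iter, len(ids)))
    for it in range(n_iter):
        A, B = _split_all(engines, rng)
        r = np.einsum("ii->i", _masked_corr_matrix(A, B)).copy()
        per_obs[it] = r
        samples[it] = _pool(r)
    per_observer = {
        oid: _pool(per_obs[:, k]) for k, oid in enumerate(ids)
    }
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return ConsistencyResult(
        mode="within",
        group=group,
        mean_r=float(np.nanmean(samples)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iter,
        per_observer_r=per_observer,
        samples=samples,
    )


def bootstrap_between(
    errors: pd.DataFrame,
    group: str,
    n_keys: int,
    n_iter: int = 1000,
    seed: int = 0,
    key: str = "stim_bin",
) -> ConsistencyResult:
    """Bootstrap the between-observer consistency of a group.

    Per iteration every observer is re-split and, for each unordered
    observer pair, one half of one observer is correlated with one half of
    the other; the pairwise correlations are pooled on the Fisher z scale
    into one sample.
    """
    ids, engines = _group_engines(errors, group, n_keys, key)
    if len(ids) < 2:
        raise ValueError("need >= 2 observers for between-observer consistency")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(ids), k=1)
    samples = np.empty(n_iter)
    for it in range(n_iter):
        A, B = _split_all(engines, rng)
        samples[it] = _pool(_masked_corr_matrix(A, B)[iu])
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return ConsistencyResult(
        mode="between",
        group=group,
        mean_r=float(np.nanmean(samples)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iter,
        samples=samples,
    )


# --------------------------------------------------------------------------
# public operations — rating design (test-retest)


def paired_phase_errors(errors: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per observer, align initial- and retest-phase errors on image id.

    Returns ``{observer_id: DataFrame(columns=[initial, retest], index=image_id)}``
    using only images the observer saw in both phases.
    """
    out: dict[str, pd.DataFrame] = {}
    for oid, sub in errors.groupby("observer_id", sort=True):
        piv = sub.pivot_table(
            index="image_id", columns="phase", values="error", aggfunc="mean"
        )
        if "initial" not in piv.columns or "retest" not in piv.columns:
            continue
        out[str(oid)] = piv[["initial", "retest"]].dropna()
    return out


def test_retest_within(errors: pd.DataFrame, observer_id: str) -> float:
    """Pearson correlation between one observer's initial-phase and
    retest-phase errors over the repeated images."""
    paired = paired_phase_errors(errors[errors["observer_id"] == observer_id])
    if observer_id not in paired or len(paired[observer_id]) < MIN_SHARED_KEYS:
        raise ValueError(
            f"observer {observer_id!r} lacks >= {MIN_SHARED_KEYS} repeated images"
        )
    piv = paired[observer_id]
    return profile_correlation(piv["initial"], piv["retest"])


def _phase_matrices(errors: pd.DataFrame, group: str):
    """Stack a group's paired phase errors into aligned matrices
    (observers x repeated images), NaN where an image is missing."""
    sub = errors[errors["group"] == group]
    paired = paired_phase_errors(sub)
    ids = sorted(paired)
    if not ids:
        raise ValueError(f"no observers with repeated images in group {group!r}")
    all_images = sorted(set().union(*(p.index for p in paired.values())))
    init = np.full((len(ids), len(all_images)), np.nan)
    retest = np.full((len(ids), len(all_images)), np.nan)
    col = {img: k for k, img in enumerate(all_images)}
    for i, oid in enumerate(ids):
        p = paired[oid]
        idx = [col[img] for img in p.index]
        init[i, idx] = p["initial"].to_numpy()
        retest[i, idx] = p["retest"].to_numpy()
    return ids, init, retest


def bootstrap_observers(
    errors: pd.DataFrame,
    group: str,
    mode: str,
    n_iter: int = 1000,
    seed: int = 0,
) -> ConsistencyResult:
    """Observer-level bootstrap of test-retest consistency (rating design).

    ``mode="within"`` resamples observers with replacement and pools their
    own initial-vs-retest correlations.  ``mode="between"`` resamples, with
    replacement, as many observer pairs as exist in the group from the set
    of all ordered pairs, correlating one observer's initial errors with
    the other's retest errors.  Pooling is on the Fisher z scale; CIs are
    95% percentile intervals.
    """
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    ids, init, retest = _phase_matrices(errors, group)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 observers in the group")
    rmat = _masked_corr_matrix(init, retest)  # (i, j): initial_i vs retest_j
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter)
    per_observer = None
    if mode == "within":
        own = np.einsum("ii->i", rmat).copy()
        for it in range(n_iter):
            take = rng.integers(0, n, size=n)
            samples[it] = _pool(own[take])
        per_observer = {oid: float(own[k]) for k, oid in enumerate(ids)}
    else:
        pairs = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
        pair_r = rmat[pairs[:, 0], pairs[:, 1]]
        n_draw = len(pairs)
        for it in range(n_iter):
            take = rng.integers(0, len(pairs), size=n_draw)
            samples[it] = _pool(pair_r[take])
    lo, hi = np.nanpercentile(samples, [2.5, 97.5])
    return ConsistencyResult(
        mode=mode,
        group=group,
        mean_r=float(np.nanmean(samples)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iter,
        per_observer_r=per_observer,
        samples=samples,
    )
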