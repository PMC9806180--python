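"""Circular morph-continuum geometry.

The stimulus space is a closed loop of morph images interpolated between a
small set of shape prototypes: ``n_prototypes`` prototype images, with
``n_morphs_per_pair`` intermediate morphs inserted between each adjacent
pair, so the loop has ``n_prototypes * (n_morphs_per_pair + 1)`` steps in
total.  Distances along the loop are measured in *morph units* (one index
step) and always along the shorter arc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusContinuum",
    "build_continuum",
    "circular_distance",
    "bin_index",
    "nearest_prototype",
]


@dataclass(frozen=True)
class StimulusContinuum:
    """Geometry of a circular morph continuum.

    Attributes
    ----------
    n_prototypes
        Number of prototype shapes anchoring the loop (>= 2).
    n_morphs_per_pair
        Number of interpolated images between each adjacent prototype pair.
    n_total
        Total number of steps on the loop,
        ``n_prototypes * (n_morphs_per_pair + 1)``.
    prototype_positions
        Indices of the prototypes, equally spaced starting at 0.
    """

    n_prototypes: int
    n_morphs_per_pair: int
    n_total: int = field(init=False)
    prototype_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_prototypes < 2:
            raise ValueError("need at least 2 prototypes to morph between")
        if self.n_morphs_per_pair < 0:
            raise ValueError("n_morphs_per_pair must be >= 0")
        spacing = self.n_morphs_per_pair + 1
        object.__setattr__(self, "n_total", self.n_prototypes * spacing)
        object.__setattr__(
            self,
            "prototype_positions",
            tuple(k * spacing for k in range(self.n_prototypes)),
        )

    @property
    def max_distance(self) -> int:
        """Largest attainable circular distance magnitude, floor(n/2)."""
        return self.n_total // 2


def build_continuum(n_prototypes: int, n_morphs_per_pair: int) -> StimulusContinuum:
    """Build a circular continuum of ``n_prototypes`` shapes with
    ``n_morphs_per_pair`` morphs between each adjacent pair.

    The standard configuration (3 prototypes, 48 morphs per pair) yields a
    147-step loop with prototypes at indices 0, 49 and 98.
    """
    return StimulusContinuum(n_prototypes, n_morphs_per_pair)


def circular_distance(i: int, j: int, n: int) -> int:
    """Signed shortest distance from index ``i`` to index ``j`` on a loop of
    length ``n``, in morph units.

    The magnitude is the length of the shorter arc, at most ``floor(n / 2)``.
    The sign is positive when the shorter arc from ``i`` to ``j`` runs in the
    increasing-index direction; an exact half-loop tie (even ``n``) is
    returned as ``+n/2``.
    """
    if n <= 0:
        raise ValueError("continuum length must be positive")
    i = int(i)
    j = int(j)
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"indices ({i}, {j}) out of range for n={n}")
    forward = (j - i) % n
    backward = (i - j) % n
    if forward <= backward:
        return forward
    return -backward


def circular_distance_array(i, j, n: int):
    """Vectorized :func:`circular_distance` over numpy arrays of indices."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise ValueError(f"indices out of range for n={n}")
    forward = (j - i) % n
    backward = (i - j) % n
    return np.where(forward <= backward, forward, -backward)


def bin_index(i: int, bin_width: int) -> int:
    """Bin a stimulus index by grouping ``bin_width`` neighbours: floor(i / w).

    Bins are anchored at index 0, so a 147-step loop binned at width 3
    yields bins 0..48 (49 bins).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    return int(i) // int(bin_width)


def n_bins(n_total: int, bin_width: int) -> int:
    """Number of bins produced by :func:`bin_index` over ``[0, n_total)``."""
    return math.ceil(n_total / bin_width)


def nearest_prototype(i: int, continuum: StimulusContinuum) -> int:
    """Category of the prototype closest to index ``i`` along the loop.

    Ties (possible only when the prototype spacing is even) go to the
    lower-numbered prototype.
    """
    n = continuum.n_total
    if not (0 <= i < n):
        raise ValueError(f"index {i} out of range for n={n}")
    dists = [abs(circular_distance(i, p, n)) for p in continuum.prototype_positions]
    return int(np.argmin(dists))
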