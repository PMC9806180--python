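"""Internal consistency and cross-experiment meta-statistics.

For a coarse, forced-choice-like view of the matching data, every stimulus
and every response is collapsed to its nearest prototype category (a 3AFC
recoding), and inter-observer agreement is summarized by Cronbach's alpha
with observers as items and stimuli as cases.  Evidence from the two task
designs is combined with Fisher's combined probability test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .continuum import StimulusContinuum, circular_distance_array

__all__ = [
    "dummy_code_3afc",
    "categorical_response_matrix",
    "cronbach_alpha",
    "fisher_combined",
]


def _nearest_prototype_array(indices: np.ndarray, continuum: StimulusContinuum):
    protos = np.asarray(continuum.prototype_positions)
    d = np.abs(
        circular_distance_array(
            indices[:, None].repeat(len(protos), axis=1),
            np.broadcast_to(protos, (len(indices), len(protos))),
            continuum.n_total,
        )
    )
    return np.argmin(d, axis=1)


def dummy_code_3afc(
    trials: pd.DataFrame, continuum: StimulusContinuum
) -> pd.DataFrame:
    """Recode matching trials to prototype categories.

    Adds ``target_category`` and ``response_category`` columns, each the
    nearest-prototype category (0..n_prototypes-1) of the respective index.
    """
    out = trials.copy()
    out["target_category"] = _nearest_prototype_array(
        trials["target_index"].to_numpy(), continuum
    )
    out["response_category"] = _nearest_prototype_array(
        trials["response_index"].to_numpy(), continuum
    )
    return out


def categorical_response_matrix(
    coded_trials: pd.DataFrame, group: str | None = None
) -> pd.DataFrame:
    """Stimuli x observers matrix of modal response categories.

    Rows are target stimulus indices, columns observers; each cell is the
    observer's modal response category for that target (ties to the lower
    code).  Targets not seen by every observer are dropped so the matrix is
    complete.
    """
    sub = coded_trials if group is None else coded_trials[coded_trials["group"] == group]

    def modal(s: pd.Series) -> int:
        counts = s.value_counts()
        top = counts[counts == counts.iloc[0]]
        return int(min(top.index))

    mat = sub.pivot_table(
        index="target_index",
        columns="observer_id",
        values="response_category",
        aggfunc=modal,
    )
    return mat.dropna(axis=0).astype(int)


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha with columns as items and rows as cases.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(row sums))`` using
    sample (ddof=1) variances.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >= 3 rows and >= 2 columns")
    if np.isnan(X).any():
        raise ValueError("matrix must be complete (no missing cells)")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def fisher_combined(p_values) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    ``chi2 = -2 * sum(log p_i)`` on ``2k`` degrees of freedom; returns
    ``(chi2, df, combined_p)``.  Requires every p in (0, 1].
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return chi2, df, float(stats.chi2.sf(chi2, df))
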