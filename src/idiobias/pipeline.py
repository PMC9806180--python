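"""End-to-end orchestration: simulate or ingest trials, analyze, report.

``run_pipeline`` composes the full analysis for either task design (or
both): trial errors, per-observer sensitivity (JND or d'), within- and
between-observer consistency with bootstrap CIs, permutation nulls with
p-values, per-group Cronbach's alpha, and — when both designs run — a
Fisher combined test of the radiologist-vs-untrained within-consistency
difference across experiments.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import consistency as cons
from . import errors as err
from . import nulls as nll
from . import observers as obs
from . import reliability as rel
from .continuum import build_continuum, n_bins

logger = logging.getLogger("idiobias")

GROUPS = ("radiologist", "untrained")

__all__ = ["RunConfig", "read_trials", "write_trials", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``simulate=True`` cohorts are generated from the embedded cohort
    configs; otherwise ``matching_path``/``rating_path`` point at trial CSVs.
    ``drop_one_repeat`` removes one repeated image from the rating-design
    retest analysis (the analyzed design used 39 of 40 repeats).
    """

    experiment: str = "both"  # matching | rating | both
    simulate: bool = True
    matching_path: str | None = None
    rating_path: str | None = None
    matching_cohort: obs.MatchingCohortConfig = field(
        default_factory=obs.MatchingCohortConfig
    )
    rating_cohort: obs.RatingCohortConfig = field(
        default_factory=obs.RatingCohortConfig
    )
    bin_width: int = 3
    n_bootstrap: int = 1000
    n_permutation: int = 10_000
    drop_one_repeat: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("matching", "rating", "both"):
            raise ValueError("experiment must be matching, rating or both")
        if min(self.bin_width, self.n_bootstrap, self.n_permutation) < 1:
            raise ValueError("all counts must be positive")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


# --------------------------------------------------------------------------
# trial-table I/O

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (UTF-8, header row)."""
    trials.to_csv(path, index=False)


def read_trials(path: str | Path, schema: str, n_total: int = 147) -> pd.DataFrame:
    """Read and validate a trial CSV of the given schema.

    ``schema`` is ``"matching"`` or ``"rating"``.  Malformed rows are
    rejected with their (1-based, header-excluded) row numbers; missing
    columns, unknown group labels, out-of-range indices or ratings all
    raise ``ValueError``.
    """
    if schema == "matching":
        required = obs.MATCHING_COLUMNS
    elif schema == "rating":
        required = obs.RATING_COLUMNS
    else:
        raise ValueError("schema must be 'matching' or 'rating'")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trial table")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask]:
            bad.setdefault(int(i) + 1, reason)

    flag(~df["group"].isin(GROUPS), "unknown group label")
    if schema == "matching":
        for col in ("target_index", "response_index"):
            vals = pd.to_numeric(df[col], errors="coerce")
            flag(
                vals.isna() | (vals < 0) | (vals >= n_total) | (vals % 1 != 0),
                f"{col} outside [0, {n_total})",
            )
    else:
        rating = pd.to_numeric(df["raw_rating"], errors="coerce")
        flag(rating.isna() | (rating < 0) | (rating > 10), "raw_rating outside [0, 10]")
        flag(~df["truth_label"].isin(["real", "gan"]), "unknown truth label")
        flag(~df["phase"].isin(["initial", "retest"]), "unknown phase")
    if bad:
        lines = "; ".join(f"row {k}: {v}" for k, v in sorted(bad.items())[:10])
        raise ValueError(f"{path}: {len(bad)} malformed rows ({lines})")
    return df


# --------------------------------------------------------------------------
# per-design analyses


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _difference_p(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Bootstrap p-value for 'group a more consistent than group b':
    fraction of iterations (plus-one corrected) where a's pooled
    correlation does not exceed b's."""
    n = min(len(samples_a), len(samples_b))
    le = int(np.sum(samples_a[:n] <= samples_b[:n]))
    return (le + 1) / (n + 1)


def analyze_matching(
    trials: pd.DataFrame,
    continuum,
    bin_width: int,
    n_bootstrap: int,
    n_permutation: int,
    seed: int,
) -> dict:
    """Full matching-design analysis: JND per observer, split-half
    within/between consistency with bootstrap CIs and shift-permutation
    nulls per group, 3AFC Cronbach's alpha per group."""
    seeds = _child_seeds(seed, 4 * len(GROUPS))
    errors = err.matching_errors(trials, continuum, bin_width)
    nb = n_bins(continuum.n_total, bin_width)
    coded = rel.dummy_code_3afc(trials, continuum)

    report: dict = {"groups": {}}
    within_samples = {}
    for gi, group in enumerate(GROUPS):
        sub = errors[errors["group"] == group]
        if sub.empty:
            report["groups"][group] = None
            continue
        logger.info("matching analysis: group=%s", group)
        s_w, s_b, s_nw, s_nb = seeds[4 * gi : 4 * gi + 4]
        within = cons.bootstrap_within(errors, group, nb, n_bootstrap, s_w)
        between = cons.bootstrap_between(errors, group, nb, n_bootstrap, s_b)
        null_w = nll.null_within_matching(errors, group, nb, n_permutation, s_nw)
        null_b = nll.null_between_matching(errors, group, nb, n_permutation, s_nb)
        jnds = {
            oid: err.estimate_jnd(sub[sub["observer_id"] == oid]["error"].to_numpy())
            for oid in sorted(sub["observer_id"].unique())
        }
        alpha = rel.cronbach_alpha(rel.categorical_response_matrix(coded, group))
        report["groups"][group] = {
            "within": within.to_jsonable(),
            "between": between.to_jsonable(),
            "null_within": null_w.to_jsonable(),
            "null_between": null_b.to_jsonable(),
            "p_within": nll.null_pvalue(within.mean_r, null_w),
            "p_between": nll.null_pvalue(between.mean_r, null_b),
            "cronbach_alpha": alpha,
            "jnd": jnds,
            "jnd_mean": float(np.mean(list(jnds.values()))),
            "jnd_sd": float(np.std(list(jnds.values()), ddof=1))
            if len(jnds) > 1
            else 0.0,
        }
        within_samples[group] = within.samples
    if all(g in within_samples for g in GROUPS):
        report["p_radiologists_more_consistent"] = _difference_p(
            within_samples["radiologist"], within_samples["untrained"]
        )
    return report


def analyze_rating(
    trials: pd.DataFrame,
    n_bootstrap: int,
    n_permutation: int,
    seed: int,
    drop_one_repeat: bool = True,
) -> dict:
    """Full rating-design analysis: normalization, d' per observer,
    test-retest within/between consistency with observer bootstrap and
    label-shuffle nulls per group, error-profile Cronbach's alpha."""
    seeds = _child_seeds(seed, 4 * len(GROUPS))
    errors = err.rating_errors(trials)
    if drop_one_repeat:
        retest_imgs = sorted(errors.loc[errors["phase"] == "retest", "image_id"].unique())
        if retest_imgs:
            dropped = retest_imgs[-1]
            errors = errors[
                ~((errors["phase"] == "retest") & (errors["image_id"] == dropped))
            ]
            logger.info("rating analysis: dropped repeat image %s", dropped)

    report: dict = {"groups": {}}
    within_samples = {}
    for gi, group in enumerate(GROUPS):
        sub = errors[errors["group"] == group]
        if sub.empty:
            report["groups"][group] = None
            continue
        logger.info("rating analysis: group=%s", group)
        s_w, s_b, s_nw, s_nb = seeds[4 * gi : 4 * gi + 4]
        within = cons.bootstrap_observers(errors, group, "within", n_bootstrap, s_w)
        between = cons.bootstrap_observers(errors, group, "between", n_bootstrap, s_b)
        null_w = nll.null_rating(errors, group, "within", n_permutation, s_nw)
        null_b = nll.null_rating(errors, group, "between", n_permutation, s_nb)
        dprimes = {
            oid: err.compute_dprime(sub[sub["observer_id"] == oid])
            for oid in sorted(sub["observer_id"].unique())
        }
        initial = sub[sub["phase"] == "initial"]
        alpha_matrix = initial.pivot_table(
            index="image_id", columns="observer_id", values="error"
        ).dropna(axis=0)
        alpha = rel.cronbach_alpha(alpha_matrix)
        report["groups"][group] = {
            "within": within.to_jsonable(),
            "between": between.to_jsonable(),
            "null_within": null_w.to_jsonable(),
            "null_between": null_b.to_jsonable(),
            "p_within": nll.null_pvalue(within.mean_r, null_w),
            "p_between": nll.null_pvalue(between.mean_r, null_b),
            "cronbach_alpha": alpha,
            "dprime": dprimes,
            "dprime_mean": float(np.mean(list(dprimes.values()))),
        }
        within_samples[group] = within.samples
    if all(g in within_samples for g in GROUPS):
        report["p_radiologists_more_consistent"] = _difference_p(
            within_samples["radiologist"], within_samples["untrained"]
        )
    return report


# --------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses and return the summary report dict.

    Deterministic given the config (identical config + seed gives an
    identical report).  If ``config.output_dir`` is set, the report is also
    written there as JSON and TSV.
    """
    logger.info("pipeline start: experiment=%s seed=%d", config.experiment, config.seed)
    report: dict = {"config": config.to_jsonable(), "seed": config.seed}
    seeds = _child_seeds(config.seed ^ 0x5EED, 4)

    if config.experiment in ("matching", "both"):
        if config.simulate:
            dataset = obs.generate_matching_cohort(config.matching_cohort, seeds[0])
            trials = dataset.trials
            continuum = dataset.continuum
        else:
            cohort = config.matching_cohort
            continuum = build_continuum(cohort.n_prototypes, cohort.n_morphs_per_pair)
            trials = read_trials(config.matching_path, "matching", continuum.n_total)
        report["matching"] = analyze_matching(
            trials,
            continuum,
            config.bin_width,
            config.n_bootstrap,
            config.n_permutation,
            seeds[1],
        )

    if config.experiment in ("rating", "both"):
        if config.simulate:
            dataset = obs.generate_rating_cohort(config.rating_cohort, seeds[2])
            trials = dataset.trials
        else:
            trials = read_trials(config.rating_path, "rating")
        report["rating"] = analyze_rating(
            trials,
            config.n_bootstrap,
            config.n_permutation,
            seeds[3],
            config.drop_one_repeat,
        )

    if "matching" in report and "rating" in report:
        p1 = report["matching"].get("p_radiologists_more_consistent")
        p2 = report["rating"].get("p_radiologists_more_consistent")
        if p1 is not None and p2 is not None:
            chi2, df, p = rel.fisher_combined([p1, p2])
            report["combined_within_consistency_difference"] = {
                "chi2": chi2,
                "df": df,
                "p": p,
            }

    if config.output_dir is not None:
        write_report(report, config.output_dir)
    logger.info("pipeline done")
    return report


def _flat_rows(report: dict):
    for experiment in ("matching", "rating"):
        section = report.get(experiment)
        if not section:
            continue
        for group, g in section["groups"].items():
            if g is None:
                continue
            for mode in ("within", "between"):
                yield {
                    "experiment": experiment,
                    "group": group,
                    "mode": mode,
                    "mean_r": g[mode]["mean_r"],
                    "ci_low": g[mode]["ci_low"],
                    "ci_high": g[mode]["ci_high"],
                    "null_upper_97_5": g[f"null_{mode}"]["upper_97_5"],
                    "p_value": g[f"p_{mode}"],
                }


def write_report(report: dict, output_dir: str | Path) -> None:
    """Write the report as sorted-key JSON plus a flat TSV summary table."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    pd.DataFrame(_flat_rows(report)).to_csv(
        out / "summary.tsv", sep="\t", index=False
    )
    logger.info("report written to %s", out)
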