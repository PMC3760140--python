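"""End-to-end orchestration of the synthetic study and its three analyses.

:func:`run_analysis` executes the full pipeline: generate (or accept) a
cohort, encode trials into stay/switch rows, score engagement on the
odd-trial rows, then fit

(a) the extraversion-moderation model on all rows,
(b) the same model on the top-engagement subgroup, even rows only,
(c) the engagement-interaction model on even rows,

and test the linear contrast comparing the engagement-by-extraversion
moderation of model-free learning (the reward three-way interaction)
against the model-based one (the four-way interaction). A structural
guard refuses any configuration in which the rows defining engagement
intersect the rows on which its effects are tested.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tsio
from .agents import (
    PopulationSpec,
    RegressionGenSpec,
    simulate_from_regression,
    simulate_population,
)
from .coding import encode_trials, split_odd_even
from .engagement import compute_engagement, select_top_fraction, zscore
from .hier_logit import ContrastResult, GlmmFit, fit_multilevel, wald_contrast
from .task import TaskConfig

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "CrossFitError",
    "stay_probability_summary",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger(__name__)

#: Contrast for model (c): engagement moderation of the extraversion-by-reward
#: (model-free) effect minus that of the extraversion-by-reward-by-transition
#: (model-based) effect.
MF_MINUS_MB_CONTRAST = {
    "rew:extraversion_z:engagement_z": 1.0,
    "trans:rew:extraversion_z:engagement_z": -1.0,
}


class CrossFitError(ValueError):
    """Engagement would be defined and tested on overlapping rows."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one end-to-end synthetic study.

    Exactly one of ``population`` / ``regression`` drives data generation
    (unless trials are supplied directly to :func:`run_analysis`).
    ``split_on`` picks the trial whose parity defines the odd/even split
    ("outcome" = trial n+1 of each pair, "predictor" = trial n);
    ``engage_split`` and ``test_split`` name the halves used to define and
    to test the engagement score and must differ.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationSpec | None = field(default_factory=PopulationSpec)
    regression: RegressionGenSpec | None = None
    seed: int = 0
    top_fraction: float = 0.2
    split_on: str = "outcome"
    engage_split: str = "odd"
    test_split: str = "even"
    include_subsample_model: bool = False

    def __post_init__(self) -> None:
        if self.engage_split not in ("odd", "even") or self.test_split not in (
            "odd",
            "even",
        ):
            raise ValueError("engage_split and test_split must be 'odd' or 'even'")
        if self.engage_split == self.test_split:
            raise CrossFitError(
                "engagement must be defined and tested on disjoint trial halves"
            )
        if self.population is not None and self.regression is not None:
            raise ValueError("specify only one of population / regression")

    def digest(self) -> str:
        import json

        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    stay_table: pd.DataFrame | None
    engagement: pd.DataFrame
    fits: dict[str, GlmmFit]
    coef_tables: dict[str, pd.DataFrame]
    contrast: ContrastResult
    covariates: pd.DataFrame
    provenance: dict


def stay_probability_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """2x2 table of stay frequency by previous reward and transition.

    Cell means are computed per subject first, then averaged over
    subjects. Rows are rewarded/unrewarded, columns common/rare; an empty
    cell yields NaN.
    """
    rows = encode_trials(trials)
    per_subject = (
        rows.groupby(["subject_id", "rew", "trans"])["stay"].mean().reset_index()
    )
    grand = per_subject.groupby(["rew", "trans"])["stay"].mean().unstack("trans")
    table = pd.DataFrame(
        {
            "common": [grand.loc[1, 1], grand.loc[-1, 1]],
            "rare": [grand.loc[1, -1], grand.loc[-1, -1]],
        },
        index=pd.Index(["rewarded", "unrewarded"], name="previous_outcome"),
    )
    return table


def check_crossfit(engage_rows: pd.DataFrame, test_rows: pd.DataFrame) -> None:
    """Raise :class:`CrossFitError` if the two row sets share any trial."""
    keys_a = set(map(tuple, engage_rows[["subject_id", "outcome_trial"]].to_numpy()))
    keys_b = set(map(tuple, test_rows[["subject_id", "outcome_trial"]].to_numpy()))
    overlap = keys_a & keys_b
    if overlap:
        raise CrossFitError(
            f"{len(overlap)} rows would be used both to define and to test "
            f"engagement (e.g. {sorted(overlap)[:3]})"
        )


def _generate(config: AnalysisConfig, rng: np.random.Generator):
    if config.regression is not None:
        spec = config.regression
        n = spec.n_subjects
        from .agents import _truncnorm  # trait emulation shared with the population route

        raw = np.array([round(_truncnorm(16.0, 5.0, 0.0, 23.0, rng)) for _ in range(n)])
        covariates = pd.DataFrame(
            {
                "subject_id": [f"s{i + 1:03d}" for i in range(n)],
                "extraversion_raw": raw,
                "extraversion_z": zscore(raw),
                "subsample": np.where(np.arange(n) < n // 2, 1, 2),
            }
        )
        rows = simulate_from_regression(spec, rng, covariates=covariates)
        return None, rows, covariates
    trials, covariates, _truth = simulate_population(config.population, config.task, rng)
    return trials, encode_trials(trials), covariates


def run_analysis(
    config: AnalysisConfig,
    trials: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> ReportBundle:
    """Run the full pipeline and return every report table.

    Supplying ``trials`` (and ``covariates``) analyzes existing data
    instead of generating a cohort; otherwise the configured generator is
    run with ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    stay_table = None
    if trials is not None:
        if covariates is None:
            raise ValueError("covariates are required when trials are supplied")
        rows = encode_trials(trials)
        stay_table = stay_probability_summary(trials)
        logger.info("stage=load n_trials=%d n_rows=%d", len(trials), len(rows))
    else:
        trials, rows, covariates = _generate(config, rng)
        if trials is not None:
            stay_table = stay_probability_summary(trials)
        logger.info("stage=generate n_rows=%d n_subjects=%d",
                    len(rows), covariates["subject_id"].nunique())

    if "extraversion_z" not in covariates.columns:
        covariates = covariates.assign(
            extraversion_z=zscore(covariates["extraversion_raw"].to_numpy())
        )

    odd_rows, even_rows = split_odd_even(rows, on=config.split_on)
    halves = {"odd": odd_rows, "even": even_rows}
    engage_rows = halves[config.engage_split]
    test_rows = halves[config.test_split]
    check_crossfit(engage_rows, test_rows)

    engagement = compute_engagement(engage_rows, fraction=config.top_fraction)
    covariates = covariates.merge(
        engagement[["subject_id", "engagement_z"]], on="subject_id", how="inner"
    )
    logger.info("stage=engagement n_scored=%d", len(engagement))

    fits: dict[str, GlmmFit] = {}
    fits["extraversion"] = fit_multilevel(
        rows, covariates, moderators=("extraversion_z",)
    )
    logger.info("stage=fit_extraversion converged=%s", fits["extraversion"].converged)

    top_ids = select_top_fraction(engagement, config.top_fraction)
    sub_rows = test_rows[test_rows["subject_id"].isin(top_ids)]
    fits["subgroup"] = fit_multilevel(
        sub_rows, covariates, moderators=("extraversion_z",)
    )
    logger.info(
        "stage=fit_subgroup n_subjects=%d converged=%s",
        len(top_ids), fits["subgroup"].converged,
    )

    fits["engagement"] = fit_multilevel(
        test_rows, covariates, moderators=("extraversion_z", "engagement_z")
    )
    logger.info("stage=fit_engagement converged=%s", fits["engagement"].converged)

    if config.include_subsample_model:
        cov = covariates.assign(
            subsample_c=np.where(covariates["subsample"] == 1, 1.0, -1.0)
        )
        fits["subsample"] = fit_multilevel(rows, cov, moderators=("subsample_c",))
        logger.info("stage=fit_subsample converged=%s", fits["subsample"].converged)

    contrast = wald_contrast(fits["engagement"], MF_MINUS_MB_CONTRAST)
    logger.info("stage=contrast chi2=%.4f p=%.4f", contrast.chi_square, contrast.pvalue)

    import twostep

    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "package_version": twostep.__version__,
        "n_rows": int(len(rows)),
        "n_subjects": int(covariates["subject_id"].nunique()),
    }
    return ReportBundle(
        stay_table=stay_table,
        engagement=engagement,
        fits=fits,
        coef_tables={name: fit.summary() for name, fit in fits.items()},
        contrast=contrast,
        covariates=covariates,
        provenance=provenance,
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write every bundle table as deterministic delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = tsio.FLOAT_FORMAT
    if bundle.stay_table is not None:
        bundle.stay_table.to_csv(outdir / "stay_probabilities.csv", float_format=ff)
    bundle.engagement.to_csv(outdir / "engagement.csv", index=False, float_format=ff)
    for name, table in bundle.coef_tables.items():
        table.to_csv(outdir / f"coefficients_{name}.csv", index=False, float_format=ff)
    pd.DataFrame([vars(bundle.contrast)]).to_csv(
        outdir / "contrast.csv", index=False, float_format=ff
    )
    bundle.covariates.to_csv(outdir / "covariates.csv", index=False, float_format=ff)
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(bundle.provenance, fh, sort_keys=True)
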