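"""Deviance-based task-engagement score and subgroup selection.

A subject's engagement is the deviance of the intercept-only logistic
model minus the deviance of the full 2x2 factorial model, fit to that
subject's odd-numbered design rows only. It is the likelihood-ratio
statistic comparing "responds to trial events through any combination of
reward and transition" against "stays or switches at a constant rate";
under the null of no responsiveness it is approximately chi-square with
3 degrees of freedom. Downstream analyses that use the score must be run
on the even-numbered rows so that the score is defined and tested on
disjoint data.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .hier_logit import fit_subject_logistic, intercept_only_deviance

__all__ = [
    "engagement_score",
    "compute_engagement",
    "select_top_fraction",
    "zscore",
    "ENGAGEMENT_COLUMNS",
]

logger = logging.getLogger(__name__)

ENGAGEMENT_COLUMNS = [
    "subject_id",
    "n_rows",
    "score",
    "rank",
    "in_top_fraction",
    "engagement_z",
]

MIN_ROWS = 8

#: |coefficient| beyond which a per-subject fit is treated as separated,
#: i.e. the unpenalized optimum is not finite and the ridge is load-bearing.
_SEPARATION_LIMIT = 15.0


def engagement_score(rows: pd.DataFrame, ridge: float = 1e-4) -> tuple[float, bool]:
    """Deviance difference (intercept-only minus full model) for one subject.

    Both models are fit to the given rows; the full model uses an L2
    ridge on the non-intercept terms to keep the optimum finite under
    separation, and the reported deviances are unpenalized. Returns
    ``(score, penalized)`` where ``penalized`` flags that the ridge was
    load-bearing (a coefficient ran to the separation limit).
    """
    fit = fit_subject_logistic(rows, ridge=ridge)
    dev0 = intercept_only_deviance(rows["stay"].to_numpy())
    penalized = bool(np.max(np.abs(fit.coefs[1:])) > _SEPARATION_LIMIT)
    return dev0 - fit.deviance, penalized


def compute_engagement(
    rows: pd.DataFrame,
    fraction: float = 0.2,
    ridge: float = 1e-4,
    min_rows: int = MIN_ROWS,
) -> pd.DataFrame:
    """Per-subject engagement table from (odd-trial) design rows.

    Subjects with fewer than ``min_rows`` rows are excluded with a logged
    warning. Ranks are 1 = most engaged, ties broken by subject-id order;
    ``in_top_fraction`` marks the ceil(fraction * N) highest scorers, and
    ``engagement_z`` standardizes the score over the included subjects.
    """
    records = []
    for sid, sub in rows.groupby("subject_id", sort=True):
        if len(sub) < min_rows:
            logger.warning(
                "subject %s excluded from engagement scoring: %d rows < %d",
                sid, len(sub), min_rows,
            )
            continue
        score, penalized = engagement_score(sub, ridge=ridge)
        if penalized:
            logger.info("subject %s: separated per-subject fit, ridge applied", sid)
        records.append({"subject_id": sid, "n_rows": len(sub), "score": score})
    if not records:
        raise ValueError("no subject had enough rows for engagement scoring")
    table = pd.DataFrame(records)
    table = table.sort_values(
        ["score", "subject_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    n_top = math.ceil(fraction * len(table)) if 0 < fraction <= 1 else None
    if n_top is None:
        raise ValueError("fraction must lie in (0, 1]")
    table["in_top_fraction"] = table["rank"] <= n_top
    table["engagement_z"] = zscore(table["score"].to_numpy())
    return table[ENGAGEMENT_COLUMNS]


def select_top_fraction(table: pd.DataFrame, fraction: float = 0.2) -> list:
    """Subject ids of the ceil(fraction * N) highest engagement scores.

    Ties are broken by subject-id order (ascending), matching the ranking
    in :func:`compute_engagement`.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty engagement table")
    n_top = math.ceil(fraction * len(table))
    ordered = table.sort_values(
        ["score", "subject_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["subject_id"].head(n_top).tolist()


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("zscore needs a 1-d array of at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant input")
    return (x - x.mean()) / sd
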