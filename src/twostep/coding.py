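"""Stay/switch coding of raw trial sequences.

Each consecutive pair of completed trials (n, n+1) contributes one
regression row: the outcome is whether the first-stage choice was repeated
on trial n+1 ("stay"), and the predictors are the reward (+1 rewarded, -1
unrewarded) and transition type (+1 common, -1 rare) of trial n, plus
their product. Pairs touching a missed trial are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["encode_trials", "split_odd_even", "DESIGN_COLUMNS"]

DESIGN_COLUMNS = ["subject_id", "outcome_trial", "stay", "rew", "trans", "rewXtrans"]


def encode_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Encode a trial table into factorial stay/switch design rows.

    One row per consecutive completed trial pair (n, n+1) within each
    subject; predictors come from trial n, the stay outcome compares the
    first-stage choices of trials n and n+1. Raises ``ValueError`` on
    duplicate (subject, trial) keys.
    """
    required = {"subject_id", "trial", "choice1", "common", "reward", "missed"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing required columns: {sorted(missing)}")
    if trials.duplicated(subset=["subject_id", "trial"]).any():
        dup = trials[trials.duplicated(subset=["subject_id", "trial"], keep=False)]
        keys = dup[["subject_id", "trial"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (subject, trial) keys: {keys[:5]}")

    df = trials.sort_values(["subject_id", "trial"], kind="mergesort").reset_index(drop=True)
    subj = df["subject_id"].to_numpy()
    trial = df["trial"].to_numpy(dtype=np.int64)
    missed = df["missed"].to_numpy(dtype=bool)
    choice1 = df["choice1"].to_numpy(dtype=object)

    n = len(df)
    valid = np.zeros(n, dtype=bool)  # True at index of trial n of a usable (n, n+1) pair
    if n > 1:
        valid[:-1] = (
            (subj[1:] == subj[:-1])
            & (trial[1:] == trial[:-1] + 1)
            & ~missed[:-1]
            & ~missed[1:]
        )
    pred = np.flatnonzero(valid)
    stay = np.array(
        [int(choice1[i + 1] == choice1[i]) for i in pred], dtype=np.int64
    )
    sub = df.iloc[pred]
    out = pd.DataFrame(
        {
            "subject_id": sub["subject_id"].to_numpy(),
            "outcome_trial": trial[pred] + 1,
            "stay": stay,
            "rew": (2 * sub["reward"].astype("int64") - 1).to_numpy(),
            "trans": (2 * sub["common"].astype("int64") - 1).to_numpy(),
        }
    )
    out["rewXtrans"] = out["rew"] * out["trans"]
    return out.reset_index(drop=True)


def split_odd_even(
    rows: pd.DataFrame, on: str = "outcome"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition design rows by trial-index parity.

    ``on="outcome"`` (default) takes parity of the outcome trial n+1;
    ``on="predictor"`` takes parity of the predictor trial n. Returns
    ``(odd_rows, even_rows)``; the two parts are disjoint and their union
    is the input.
    """
    if on not in ("outcome", "predictor"):
        raise ValueError("on must be 'outcome' or 'predictor'")
    idx = rows["outcome_trial"] if on == "outcome" else rows["outcome_trial"] - 1
    odd_mask = idx % 2 == 1
    return (
        rows[odd_mask].reset_index(drop=True),
        rows[~odd_mask].reset_index(drop=True),
    )
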