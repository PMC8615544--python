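"""Psychomotor vigilance task (PVT) outcomes and lens transmittance deltas.

PVT logs are reduced to the standard sustained-attention outcome set: mean
RT, median RT, and the means of the fastest and slowest 10% of responses.
The first three stimuli of every session are warm-up and are discarded;
false starts and responses slower than 1 s ("too slow") are excluded from
all outcomes by default.

The blue-light transmittance delta is computed per subject from the eye
with the higher transmittance in each session: delta = max(post eyes) -
max(pre eyes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PairedSample, paired_ttest_parametric

__all__ = [
    "PvtSummary",
    "summarize_pvt",
    "compare_sessions_pvt",
    "transmittance_delta",
    "PVT_OUTCOMES",
]

PVT_OUTCOMES = ("mean_rt", "median_rt", "fastest10_mean", "slowest10_mean")

N_WARMUP_TRIALS = 3
TOO_SLOW_MS = 1000.0


@dataclass(frozen=True)
class PvtSummary:
    """Session-level PVT outcomes in milliseconds."""

    mean_rt: float
    median_rt: float
    fastest10_mean: float
    slowest10_mean: float
    n_valid: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rt": self.mean_rt,
            "median_rt": self.median_rt,
            "fastest10_mean": self.fastest10_mean,
            "slowest10_mean": self.slowest10_mean,
        }


def summarize_pvt(
    log: pd.DataFrame,
    *,
    include_too_slow: bool = False,
) -> PvtSummary:
    """Reduce a trial log to the four PVT outcomes.

    Drops the first three trials by index, then keeps ``valid`` trials
    (``too_slow`` responses are included only when ``include_too_slow``;
    false starts never).  The decile used for the fastest/slowest means
    contains max(1, round(0.1 * n_valid)) trials.
    """
    required = {"trial", "rt_ms", "flag"}
    if not required.issubset(log.columns):
        raise ValueError(f"PVT log must have columns {sorted(required)}")
    if len(log) < N_WARMUP_TRIALS + 10:
        raise ValueError(
            f"need at least {N_WARMUP_TRIALS + 10} trials, got {len(log)}"
        )
    retained = log.sort_values("trial").iloc[N_WARMUP_TRIALS:]
    keep_flags = {"valid", "too_slow"} if include_too_slow else {"valid"}
    rts = retained.loc[retained["flag"].isin(keep_flags), "rt_ms"].to_numpy(
        dtype=np.float64
    )
    n_valid = len(rts)
    if n_valid < 10:
        raise ValueError(
            f"only {n_valid} valid trials after discarding warm-up and "
            f"invalid responses; need at least 10"
        )
    k = max(1, int(np.floor(0.1 * n_valid + 0.5)))
    rts_sorted = np.sort(rts)
    return PvtSummary(
        mean_rt=float(rts.mean()),
        median_rt=float(np.median(rts)),
        fastest10_mean=float(rts_sorted[:k].mean()),
        slowest10_mean=float(rts_sorted[-k:].mean()),
        n_valid=n_valid,
    )


def compare_sessions_pvt(
    pre: dict[str, PvtSummary], post: dict[str, PvtSummary]
) -> pd.DataFrame:
    """Paired t-tests on each PVT outcome across sessions.

    ``pre`` and ``post`` map subject id -> session summary; only subjects
    present in both sessions are used.  Returns one row per outcome with
    t, two-sided p, and the direction of the change (positive t = slower
    before surgery).
    """
    subjects = sorted(set(pre) & set(post))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects with both sessions")
    rows = []
    for outcome in PVT_OUTCOMES:
        sample = PairedSample(
            pre=[getattr(pre[s], outcome) for s in subjects],
            post=[getattr(post[s], outcome) for s in subjects],
            subject_ids=subjects,
        )
        t, p = paired_ttest_parametric(sample)
        rows.append(
            {
                "outcome": outcome,
                "n": sample.n,
                "t_stat": t,
                "p_value": p,
                "direction": "pre_slower" if t > 0 else "post_slower",
                "mean_delta_ms": float(np.mean(sample.differences)),
            }
        )
    return pd.DataFrame(rows)


def transmittance_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject blue-light transmittance change.

    Input is long form with columns subject, eye, pre_pct, post_pct (one
    row per eye; a missing eye may simply be absent or NaN).  The eye with
    the higher transmittance is selected independently pre and post, and
    delta = selected post - selected pre.  Subjects with no pre or no post
    measurement raise.

    Returns one row per subject: pre_pct, post_pct, delta_pct and which
    eye was selected in each session.
    """
    required = {"subject", "eye", "pre_pct", "post_pct"}
    if not required.issubset(table.columns):
        raise ValueError(f"transmittance table must have columns {sorted(required)}")
    bad_pre = table["pre_pct"].dropna()
    bad_post = table["post_pct"].dropna()
    if ((bad_pre < 0) | (bad_pre > 100)).any() or ((bad_post < 0) | (bad_post > 100)).any():
        raise ValueError("transmittance values must lie in [0, 100] %")
    rows = []
    for subj, grp in table.groupby("subject", sort=True):
        pre_vals = grp[["eye", "pre_pct"]].dropna()
        post_vals = grp[["eye", "post_pct"]].dropna()
        if pre_vals.empty:
            raise ValueError(f"subject {subj}: no pre-surgery transmittance")
        if post_vals.empty:
            raise ValueError(f"subject {subj}: no post-surgery transmittance")
        pre_row = pre_vals.loc[pre_vals["pre_pct"].idxmax()]
        post_row = post_vals.loc[post_vals["post_pct"].idxmax()]
        rows.append(
            {
                "subject": subj,
                "pre_pct": float(pre_row["pre_pct"]),
                "post_pct": float(post_row["post_pct"]),
                "delta_pct": float(post_row["post_pct"] - pre_row["pre_pct"]),
                "pre_eye": pre_row["eye"],
                "post_eye": post_row["eye"],
                "n_eyes_pre": len(pre_vals),
                "n_eyes_post": len(post_vals),
            }
        )
    return pd.DataFrame(rows)
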