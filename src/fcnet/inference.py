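"""Group-level statistics for paired-session graph metrics.

The paired design (every subject scanned pre- and post-intervention) is
tested non-parametrically: the observed statistic is the paired t on the
within-subject differences, and its null distribution is built by randomly
flipping the sign of each subject's difference — under the null hypothesis
of exchangeable sessions, every sign pattern is equally likely.  Two-sided
p-values use the (b + 1) / (B + 1) convention so no p is ever exactly zero.

Per-region tests are corrected with Benjamini–Hochberg FDR within each
(metric, threshold) family, matching how per-threshold results are usually
reported.  Behavioral associations are plain Pearson correlations on
per-subject session deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graphs import GLOBAL_METRICS, LOCAL_METRICS

__all__ = [
    "PairedSample",
    "paired_permutation_test",
    "bh_fdr",
    "run_group_analysis",
    "correlate_deltas",
    "paired_ttest_parametric",
]

DIRECTION_PRE = "pre>post"
DIRECTION_POST = "post>pre"


@dataclass
class PairedSample:
    """Per-subject pre/post values aligned by subject id.

    Pairs where either value is missing (NaN) are excluded; the number
    excluded is kept on the instance.
    """

    pre: np.ndarray
    post: np.ndarray
    subject_ids: tuple[str, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=np.float64)
        post = np.asarray(self.post, dtype=np.float64)
        ids = tuple(str(s) for s in self.subject_ids)
        if not (len(pre) == len(post) == len(ids)):
            raise ValueError("pre, post and subject_ids must have equal length")
        keep = ~(np.isnan(pre) | np.isnan(post))
        self.n_excluded += int((~keep).sum())
        self.pre = pre[keep]
        self.post = post[keep]
        self.subject_ids = tuple(s for s, k in zip(ids, keep) if k)
        if len(self.pre) < 2:
            raise ValueError("need at least 2 complete pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.pre - self.post

    @property
    def n(self) -> int:
        return len(self.pre)


def _t_from_diffs(d: np.ndarray) -> float:
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    return float(d.mean() / (sd / np.sqrt(n)))


def _sign_flip_t(
    D: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted paired-t for each column of an n x m difference matrix.

    Sign flips leave sum(d_i^2) unchanged, so only the flipped means are
    recomputed: t = mean / sqrt((ss/n - mean^2) / (n-1) / n) column-wise.
    """
    n, m = D.shape
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    ss = np.sum(D * D, axis=0)  # invariant under flips

    def t_of(means: np.ndarray) -> np.ndarray:
        var = (ss - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n)
        # all-zero differences: mean 0, var 0 -> define t = 0
        return np.where((means == 0) & (var == 0), 0.0, t)

    t_obs = t_of(D.mean(axis=0))
    t_perm = t_of(signs @ D / n)
    return t_obs, t_perm


def paired_permutation_test(
    sample: PairedSample,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Sign-flip permutation paired t-test; returns (t statistic, two-sided p).

    All-zero differences make the statistic undefined; by convention t = 0
    and p = 1 are returned.  The smallest attainable p is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    d = sample.differences[:, None]
    if np.all(d == 0):
        return 0.0, 1.0
    t_obs, t_perm = _sign_flip_t(d, n_perm, rng)
    b = int(np.sum(np.abs(t_perm[:, 0]) >= np.abs(t_obs[0])))
    return float(t_obs[0]), (b + 1) / (n_perm + 1)


def bh_fdr(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up correction.

    Returns (adjusted p-values, rejection flags); a hypothesis is rejected
    when its adjusted p falls strictly below ``q``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def run_group_analysis(
    metrics: pd.DataFrame,
    *,
    n_perm: int = 5000,
    seed: int | None = None,
    q: float = 0.05,
    pool_thresholds: bool = False,
) -> pd.DataFrame:
    """Permutation tests for every (metric, threshold, region) plus globals.

    ``metrics`` is the tidy table produced by :func:`fcnet.graphs.metric_sweep`
    stacked over subjects and sessions, with sessions labelled ``pre`` and
    ``post``.  Subjects missing either session are excluded with a warning
    column in the result.  FDR is applied within each (metric, threshold)
    family across regions; ``pool_thresholds=True`` instead pools one
    family per metric across all thresholds.  Missing metric values
    (undefined assortativity) drop the affected subjects pairwise.

    Returns one row per test: metric, threshold, scope, n, t_stat, p_perm,
    p_fdr, significant, direction.
    """
    required = {"subject", "session", "threshold", "scope", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    sessions = set(metrics["session"].unique())
    if not {"pre", "post"}.issubset(sessions):
        raise ValueError(f"need sessions 'pre' and 'post', got {sorted(sessions)}")

    try:
        wide = (
            metrics.set_index(["metric", "threshold", "scope", "session", "subject"])[
                "value"
            ].unstack(["session", "subject"])
        )
    except ValueError as exc:
        raise ValueError(f"duplicate (metric, threshold, scope, session, subject) rows: {exc}")
    pre_w = wide["pre"]
    post_w = wide["post"]
    common = [s for s in pre_w.columns if s in set(post_w.columns)]
    n_unpaired = len(set(pre_w.columns) ^ set(post_w.columns))
    pre_w = pre_w[common]
    post_w = post_w[common]

    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    known = tuple(LOCAL_METRICS) + tuple(GLOBAL_METRICS)
    fams = sorted(
        {(m, t) for m, t, _ in wide.index if m in known},
        key=lambda mt: (known.index(mt[0]), mt[1]),
    )
    for (metric, thr), child in zip(fams, ss.spawn(len(fams))):
        rng = np.random.default_rng(child)
        idx = [
            key for key in wide.index if key[0] == metric and key[1] == thr
        ]
        scopes = [key[2] for key in idx]
        P = pre_w.loc[idx].to_numpy()  # tests x subjects
        Q = post_w.loc[idx].to_numpy()
        t_list, p_list, n_list = [], [], []
        valid = ~(np.isnan(P) | np.isnan(Q))
        D_full = P - Q
        complete = valid.all(axis=1)
        # vectorize the (typical) complete-case block in one draw batch
        if complete.any():
            t_obs, t_perm = _sign_flip_t(D_full[complete].T, n_perm, rng)
            exceed = (np.abs(t_perm) >= np.abs(t_obs)).sum(axis=0)
            p_c = (exceed + 1) / (n_perm + 1)
            p_c = np.where((t_obs == 0) & (D_full[complete] == 0).all(axis=1), 1.0, p_c)
        ci = 0
        for k in range(len(idx)):
            if complete[k]:
                t_list.append(t_obs[ci])
                p_list.append(p_c[ci])
                n_list.append(D_full.shape[1])
                ci += 1
            else:
                d = D_full[k][valid[k]]
                if len(d) < 2:
                    t_list.append(np.nan)
                    p_list.append(np.nan)
                    n_list.append(len(d))
                    continue
                samp = PairedSample(
                    pre=P[k][valid[k]],
                    post=Q[k][valid[k]],
                    subject_ids=[str(s) for s in np.array(common)[valid[k]]],
                )
                t, p = paired_permutation_test(samp, n_perm=n_perm, seed=rng)
                t_list.append(t)
                p_list.append(p)
                n_list.append(samp.n)
        for scope, t, p, nn in zip(scopes, t_list, p_list, n_list):
            rows.append(
                {
                    "metric": metric,
                    "threshold": thr,
                    "scope": scope,
                    "n": nn,
                    "t_stat": t,
                    "p_perm": p,
                    "n_unpaired_excluded": n_unpaired,
                }
            )

    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    fam_cols = ["metric"] if pool_thresholds else ["metric", "threshold"]
    for _, grp in out.groupby(fam_cols):
        testable = grp.index[grp["p_perm"].notna()]
        if len(testable) == 0:
            continue
        p_adj, rej = bh_fdr(out.loc[testable, "p_perm"].to_numpy(), q=q)
        out.loc[testable, "p_fdr"] = p_adj
        out.loc[testable, "significant"] = rej
    out["direction"] = np.where(out["t_stat"] > 0, DIRECTION_PRE, DIRECTION_POST)
    out.loc[out["t_stat"].isna() | (out["t_stat"] == 0), "direction"] = ""
    return out.sort_values(
        ["metric", "threshold", "scope"], ignore_index=True
    )


def correlate_deltas(
    metric_delta: Sequence[float], behavior_delta: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-subject metric and behavior deltas.

    Two-sided p from the exact t transform t = r sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(metric_delta, dtype=np.float64)
    y = np.asarray(behavior_delta, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("deltas must be 1-D and aligned")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the delta vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest_parametric(sample: PairedSample) -> tuple[float, float]:
    """Classical paired t-test (n - 1 df, two-sided)."""
    d = sample.differences
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance in paired differences: t undefined")
    res = stats.ttest_rel(sample.pre, sample.post)
    return float(res.statistic), float(res.pvalue)
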