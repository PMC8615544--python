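"""Configuration-driven orchestration: simulate/load -> connectome -> graphs
-> group statistics -> behavioral tests -> brain-behavior correlations.

A run is fully described by a :class:`RunConfig` (loadable from YAML or
JSON).  Every stage writes its outputs under the run directory so partial
re-runs and audits are possible, and a provenance JSON echoes the exact
configuration, seed and package version.  Given the same config and seed,
all report tables are byte-identical across runs; the wall-clock timestamp
lives only in the provenance file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral import (
    PVT_OUTCOMES,
    compare_sessions_pvt,
    summarize_pvt,
    transmittance_delta,
)
from .connectome import (
    RoiTimeSeries,
    bandpass_filter,
    compute_connectivity,
    discard_initial_volumes,
    regress_confounds,
)
from .graphs import SparsityGrid, metric_sweep
from .inference import (
    DIRECTION_POST,
    DIRECTION_PRE,
    bh_fdr,
    correlate_deltas,
    run_group_analysis,
)
from .synthetic import (
    CohortSpec,
    PvtSpec,
    TransmittanceSpec,
    generate_cohort,
    generate_pvt_log,
    generate_transmittance,
)

__all__ = ["RunConfig", "run_pipeline", "make_report", "load_config"]

logger = logging.getLogger("fcnet.pipeline")

SESSIONS = ("pre", "post")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    out_dir: str
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" | "files"
    # synthetic mode
    cohort: dict = field(default_factory=dict)  # CohortSpec kwargs (seed derived)
    pvt: dict = field(default_factory=dict)  # shared PvtSpec kwargs
    pvt_post_shift_ms: float = -30.0  # added to mu for the post session
    transmittance: dict = field(default_factory=dict)  # TransmittanceSpec kwargs
    # files mode
    input_dir: str | None = None
    tr_seconds: float = 2.0
    # temporal preprocessing (files mode; synthetic series are already clean)
    n_discard: int = 10
    bandpass: tuple[float, float] | None = (0.01, 0.08)
    regress_global_signal: bool = False
    # graph + statistics stage
    sparsity: list[float] = field(default_factory=lambda: list(SparsityGrid().values))
    absolute_threshold: bool = False
    n_perm: int = 5000
    q: float = 0.05
    pool_thresholds: bool = False
    include_too_slow: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        SparsityGrid(tuple(self.sparsity))  # validate
        if self.n_perm < 1 or not (0 < self.q < 1):
            raise ValueError("need n_perm >= 1 and q in (0, 1)")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig(**data)


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds, each below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _load_timeseries_dir(cfg: RunConfig) -> dict[tuple[str, str], RoiTimeSeries]:
    """Read <subject>_<session>_timeseries.tsv files from input_dir."""
    root = Path(cfg.input_dir)
    out: dict[tuple[str, str], RoiTimeSeries] = {}
    for path in sorted(root.glob("*_timeseries.tsv")):
        stem = path.name[: -len("_timeseries.tsv")]
        try:
            subj, sess = stem.rsplit("_", 1)
        except ValueError as exc:
            raise ValueError(f"cannot parse subject/session from {path.name}") from exc
        if sess not in SESSIONS:
            raise ValueError(f"unknown session {sess!r} in {path.name}")
        out[(subj, sess)] = RoiTimeSeries.from_tsv(
            path, subject_id=subj, session=sess, tr_seconds=cfg.tr_seconds
        )
    if not out:
        raise ValueError(f"no *_timeseries.tsv files found in {root}")
    return out


def _preprocess(ts: RoiTimeSeries, cfg: RunConfig) -> RoiTimeSeries:
    if cfg.n_discard:
        ts = discard_initial_volumes(ts, cfg.n_discard)
    confounds = None
    if cfg.regress_global_signal:
        confounds = ts.data.mean(axis=1)[:, None]
    ts = regress_confounds(ts, confounds)
    if cfg.bandpass is not None:
        low, high = cfg.bandpass
        ts = bandpass_filter(ts, low, high)
    return ts


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write all outputs under ``config.out_dir``.

    Returns the main tables (group results, significant rows, PVT tests,
    correlations) keyed by name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed, 4)

    # ------------------------------------------------------------------ inputs
    if config.mode == "synthetic":
        cohort_spec = CohortSpec(**{**config.cohort, "seed": seeds[0]})
        cohort = generate_cohort(cohort_spec)
        series = cohort.timeseries
        subjects = cohort.subject_ids
        logger.info("simulated cohort: %d subjects", len(subjects))

        pvt_logs: dict[tuple[str, str], pd.DataFrame] = {}
        pvt_seed_stream = _derived_seeds(seeds[1], 2 * len(subjects))
        base_pvt = dict(config.pvt)
        for i, subj in enumerate(subjects):
            for j, sess in enumerate(SESSIONS):
                kwargs = dict(base_pvt)
                if sess == "post":
                    kwargs["exgaussian_mu_ms"] = (
                        kwargs.get("exgaussian_mu_ms", PvtSpec.exgaussian_mu_ms)
                        + config.pvt_post_shift_ms
                    )
                kwargs["seed"] = pvt_seed_stream[2 * i + j]
                pvt_logs[(subj, sess)] = generate_pvt_log(PvtSpec(**kwargs))

        trans_spec = TransmittanceSpec(
            **{**config.transmittance, "n_subjects": len(subjects), "seed": seeds[2]}
        )
        trans_raw = generate_transmittance(trans_spec)
        # align generated subject names with the cohort's
        trans_raw["subject"] = [
            subjects[int(s[3:]) - 1] for s in trans_raw["subject"]
        ]
        preprocess = False
    else:
        series = _load_timeseries_dir(config)
        subjects = tuple(sorted({s for s, _ in series}))
        pvt_logs = {}
        root = Path(config.input_dir)
        for path in sorted(root.glob("*_pvt.tsv")):
            subj, sess = path.name[: -len("_pvt.tsv")].rsplit("_", 1)
            pvt_logs[(subj, sess)] = pd.read_csv(path, sep="\t")
        trans_path = root / "transmittance.tsv"
        trans_raw = (
            pd.read_csv(trans_path, sep="\t") if trans_path.exists() else None
        )
        preprocess = True

    # ------------------------------------------------------- connectome stage
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    metric_frames = []
    grid = SparsityGrid(tuple(config.sparsity))
    for (subj, sess), ts in sorted(series.items()):
        if preprocess:
            ts = _preprocess(ts, config)
        C = compute_connectivity(ts)
        C.to_tsv(conn_dir / f"{subj}_{sess}_connectivity.tsv")
        metric_frames.append(
            metric_sweep(
                C,
                grid,
                subject_id=subj,
                session=sess,
                absolute=config.absolute_threshold,
            )
        )
        logger.info("connectome+metrics done: %s %s", subj, sess)
    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    # -------------------------------------------------------- group statistics
    group = run_group_analysis(
        metrics,
        n_perm=config.n_perm,
        seed=seeds[3],
        q=config.q,
        pool_thresholds=config.pool_thresholds,
    )
    group.to_csv(out / "group_results.tsv", sep="\t", index=False)
    significant = group[group["significant"]].reset_index(drop=True)

    # ------------------------------------------------------- behavioral stage
    pvt_tests = None
    pvt_deltas = None
    if pvt_logs:
        summaries: dict[str, dict[str, object]] = {"pre": {}, "post": {}}
        summary_rows = []
        for (subj, sess), log in sorted(pvt_logs.items()):
            s = summarize_pvt(log, include_too_slow=config.include_too_slow)
            summaries[sess][subj] = s
            summary_rows.append({"subject": subj, "session": sess, **s.as_dict(),
                                 "n_valid": s.n_valid})
        pd.DataFrame(summary_rows).to_csv(
            out / "pvt_summaries.tsv", sep="\t", index=False
        )
        pvt_tests = compare_sessions_pvt(summaries["pre"], summaries["post"])
        pvt_tests.to_csv(out / "pvt_tests.tsv", sep="\t", index=False)
        paired = sorted(set(summaries["pre"]) & set(summaries["post"]))
        pvt_deltas = pd.Series(
            {
                s: summaries["post"][s].mean_rt - summaries["pre"][s].mean_rt
                for s in paired
            },
            name="pvt_mean_rt_delta_ms",
        )

    trans_table = None
    if trans_raw is not None:
        trans_table = transmittance_delta(trans_raw)
        trans_table.to_csv(out / "transmittance.tsv", sep="\t", index=False)

    # -------------------------------------------------- behavior correlations
    correlations = _correlate_significant(
        metrics, significant, trans_table, pvt_deltas, q=config.q
    )
    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- reporting
    report_text = make_report(group, pvt_tests, correlations)
    (out / "report.txt").write_text(report_text)
    significant.to_csv(out / "significant.tsv", sep="\t", index=False)

    provenance = {
        "package": "fcnet",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.as_dict(),
        "derived_seeds": seeds,
        "n_subjects": len(subjects),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

    return {
        "metrics": metrics,
        "group_results": group,
        "significant": significant,
        "pvt_tests": pvt_tests,
        "transmittance": trans_table,
        "correlations": correlations,
    }


def _metric_delta_by_subject(
    metrics: pd.DataFrame, metric: str, threshold: float, scope: str
) -> pd.Series:
    """Per-subject post - pre metric value for one (metric, threshold, region)."""
    sel = metrics[
        (metrics["metric"] == metric)
        & (metrics["threshold"] == threshold)
        & (metrics["scope"] == scope)
    ]
    wide = sel.pivot_table(index="subject", columns="session", values="value")
    return (wide["post"] - wide["pre"]).rename("metric_delta")


def _correlate_significant(
    metrics: pd.DataFrame,
    significant: pd.DataFrame,
    trans_table: pd.DataFrame | None,
    pvt_deltas: pd.Series | None,
    *,
    q: float,
) -> pd.DataFrame:
    """Correlate every significant graph-metric delta with the behavioral deltas.

    Reports the uncorrected two-sided p and a BH-adjusted p within each
    behavior family.
    """
    behaviors: dict[str, pd.Series] = {}
    if trans_table is not None:
        behaviors["transmittance_delta_pct"] = trans_table.set_index("subject")[
            "delta_pct"
        ]
    if pvt_deltas is not None:
        behaviors["pvt_mean_rt_delta_ms"] = pvt_deltas
    rows = []
    for behavior, bseries in behaviors.items():
        for _, res in significant.iterrows():
            if res["scope"] == "global":
                continue
            mdelta = _metric_delta_by_subject(
                metrics, res["metric"], res["threshold"], res["scope"]
            )
            joined = pd.concat([mdelta, bseries.rename("behavior")], axis=1).dropna()
            try:
                r, p = correlate_deltas(
                    joined["metric_delta"].to_numpy(), joined["behavior"].to_numpy()
                )
            except ValueError:
                continue
            rows.append(
                {
                    "behavior": behavior,
                    "metric": res["metric"],
                    "threshold": res["threshold"],
                    "scope": res["scope"],
                    "n": len(joined),
                    "r": r,
                    "p_uncorrected": p,
                }
            )
    corr = pd.DataFrame(
        rows,
        columns=[
            "behavior", "metric", "threshold", "scope", "n", "r", "p_uncorrected",
        ],
    )
    corr["p_fdr"] = np.nan
    corr["significant_fdr"] = False
    for _, grp in corr.groupby("behavior"):
        p_adj, rej = bh_fdr(grp["p_uncorrected"].to_numpy(), q=q)
        corr.loc[grp.index, "p_fdr"] = p_adj
        corr.loc[grp.index, "significant_fdr"] = rej
    return corr


_DIRECTION_HEADINGS = (
    (DIRECTION_PRE, "Preoperative-Postoperative"),
    (DIRECTION_POST, "Postoperative-Preoperative"),
)


def make_report(
    group: pd.DataFrame,
    pvt_tests: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
) -> str:
    """Human-readable run report.

    Significant region results are grouped by direction of the session
    difference (pre > post first), then region, then threshold, one line
    per (region, threshold, metric) with its FDR-adjusted p.
    """
    lines: list[str] = []
    lines.append("Significant graph-metric session differences (FDR-corrected)")
    lines.append("=" * 62)
    sig = group[group["significant"].astype(bool)]
    if sig.empty:
        lines.append("(none)")
    for direction, heading in _DIRECTION_HEADINGS:
        block = sig[sig["direction"] == direction]
        if block.empty:
            continue
        lines.append("")
        lines.append(heading)
        lines.append("-" * len(heading))
        for scope in sorted(block["scope"].unique()):
            for _, row in (
                block[block["scope"] == scope]
                .sort_values(["threshold", "metric"])
                .iterrows()
            ):
                lines.append(
                    f"  {scope:<12s} threshold {row['threshold']:.2f}  "
                    f"{row['metric']:<22s} p_fdr = {row['p_fdr']:.4g}"
                )
    if pvt_tests is not None and not pvt_tests.empty:
        lines.append("")
        lines.append("PVT session comparison (paired t)")
        lines.append("-" * 33)
        for _, row in pvt_tests.iterrows():
            lines.append(
                f"  {row['outcome']:<15s} t = {row['t_stat']:+.3f}  "
                f"p = {row['p_value']:.4g}  mean delta = "
                f"{row['mean_delta_ms']:+.1f} ms ({row['direction']})"
            )
    if correlations is not None and not correlations.empty:
        lines.append("")
        lines.append("Brain-behavior correlations (significant metric deltas)")
        lines.append("-" * 55)
        shown = correlations.sort_values("p_uncorrected").head(20)
        for _, row in shown.iterrows():
            lines.append(
                f"  {row['behavior']:<26s} {row['scope']:<12s} "
                f"thr {row['threshold']:.2f} {row['metric']:<22s} "
                f"r = {row['r']:+.3f}  p = {row['p_uncorrected']:.4g}"
            )
    lines.append("")
    return "\n".join(lines)
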