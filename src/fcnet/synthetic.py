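"""Synthetic paired-session cohorts with known ground truth.

Generates everything the downstream stages consume, so the whole pipeline
can be exercised and calibrated without access to the study's raw data:

* region-mean BOLD time series for a two-session cohort, drawn from
  zero-mean multivariate normals with a block-modular correlation
  structure and an optional planted session effect on designated regions;
* psychomotor vigilance task (PVT) trial logs with ex-Gaussian reaction
  times, false starts, and the 1 s "too slow" cutoff;
* per-eye blue-light transmittance tables for the two intraocular lens
  classes (blue-filter 68% vs clear 95% around 475 nm);
* toy 4D volumes with an integer label image for parcellation tests.

Every generator takes an explicit seed and is bit-reproducible; ground
truth (the exact population correlation matrices, the planted shifts) is
returned alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import RoiTimeSeries

__all__ = [
    "CohortSpec",
    "PvtSpec",
    "TransmittanceSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_pvt_log",
    "generate_transmittance",
    "generate_toy_volume",
    "modular_correlation",
    "planted_effect_correlation",
]

#: post-surgery blue-light transmittance (%) by intraocular lens class
IOL_TRANSMITTANCE = {"blue_filter": 68.0, "clear": 95.0}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a paired-session imaging cohort.

    Defaults mirror the study design this package reanalyses: 34 subjects,
    116 atlas regions, 290 retained volumes at TR 2 s.  The planted session
    effect shifts, in the post session only, every off-diagonal correlation
    involving ``effect_regions`` by ``effect_delta_corr`` (then re-projects
    to the nearest positive-definite correlation matrix).
    """

    n_subjects: int = 34
    n_regions: int = 116
    n_timepoints: int = 290
    tr_seconds: float = 2.0
    n_communities: int = 8
    within_community_corr: float = 0.35
    between_community_corr: float = 0.05
    effect_regions: tuple[int, ...] = ()
    effect_delta_corr: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.n_regions, self.n_timepoints) < 2:
            raise ValueError("n_regions and n_timepoints must be >= 2")
        if not (0 <= self.between_community_corr < self.within_community_corr < 1):
            raise ValueError(
                "need 0 <= between_community_corr < within_community_corr < 1, got "
                f"between={self.between_community_corr}, within={self.within_community_corr}"
            )
        if not 1 <= self.n_communities <= self.n_regions:
            raise ValueError("n_communities must lie in [1, n_regions]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        regions = tuple(int(r) for r in self.effect_regions)
        if any(not 1 <= r <= self.n_regions for r in regions):
            raise ValueError(
                f"effect_regions must be 1-based indices in [1, {self.n_regions}]"
            )
        object.__setattr__(self, "effect_regions", regions)

    @property
    def region_labels(self) -> tuple[str, ...]:
        width = len(str(self.n_regions))
        return tuple(f"ROI{r:0{width}d}" for r in range(1, self.n_regions + 1))


@dataclass(frozen=True)
class PvtSpec:
    """Single-session PVT design: 5 min, ITI uniform on [2, 10] s, 1 s cutoff."""

    duration_seconds: float = 300.0
    iti_range_seconds: tuple[float, float] = (2.0, 10.0)
    exgaussian_mu_ms: float = 280.0
    exgaussian_sigma_ms: float = 40.0
    exgaussian_tau_ms: float = 80.0
    false_start_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.iti_range_seconds
        if not (0 < lo <= hi):
            raise ValueError(f"ITI range must satisfy 0 < low <= high, got ({lo}, {hi})")
        if self.duration_seconds <= 0:
            raise ValueError("duration must be positive")
        if self.exgaussian_mu_ms <= 0 or self.exgaussian_sigma_ms < 0 or self.exgaussian_tau_ms < 0:
            raise ValueError("ex-Gaussian parameters must be positive (sigma, tau >= 0)")
        if not 0 <= self.false_start_rate < 1:
            raise ValueError("false_start_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TransmittanceSpec:
    """Blue-light transmittance cohort: yellowed natural lenses pre, IOL class post."""

    n_subjects: int = 34
    pre_mean: float = 35.0
    pre_sd: float = 12.0
    iol_filter_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.pre_mean <= 100 or self.pre_sd < 0:
            raise ValueError("pre_mean must lie in [0, 100] and pre_sd be non-negative")
        if not 0 <= self.iol_filter_fraction <= 1:
            raise ValueError("iol_filter_fraction must lie in [0, 1]")


def modular_correlation(spec: CohortSpec) -> np.ndarray:
    """Block-modular population correlation matrix for the pre session.

    Regions are split into ``n_communities`` contiguous blocks; correlation
    is ``within_community_corr`` inside a block and ``between_community_corr``
    across blocks, unit diagonal.
    """
    R = spec.n_regions
    comm = np.array_split(np.arange(R), spec.n_communities)
    C = np.full((R, R), spec.between_community_corr)
    for block in comm:
        C[np.ix_(block, block)] = spec.within_community_corr
    np.fill_diagonal(C, 1.0)
    _assert_positive_definite(C, spec, session="pre")
    return C


def nearest_correlation_pd(C: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalue clipping at ``min_eig`` followed by re-standardisation to a
    unit diagonal.
    """
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    w = np.clip(w, min_eig, None)
    M = (V * w) @ V.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return M


def planted_effect_correlation(spec: CohortSpec) -> np.ndarray:
    """Post-session population correlation: pre structure plus the planted shift.

    Off-diagonal entries in the rows/columns of every effect region are
    shifted by ``effect_delta_corr`` (clipped into [-0.99, 0.99]) and the
    result is projected back to the nearest positive-definite correlation
    matrix so it remains a valid sampling target.
    """
    C = modular_correlation(spec)
    if not spec.effect_regions or spec.effect_delta_corr == 0.0:
        return C
    C = C.copy()
    idx = np.array([r - 1 for r in spec.effect_regions])
    mask = np.zeros_like(C, dtype=bool)
    mask[idx, :] = True
    mask[:, idx] = True
    np.fill_diagonal(mask, False)
    C[mask] = np.clip(C[mask] + spec.effect_delta_corr, -0.99, 0.99)
    C = nearest_correlation_pd(C)
    _assert_positive_definite(C, spec, session="post")
    return C


def _assert_positive_definite(C: np.ndarray, spec: CohortSpec, session: str) -> None:
    w_min = float(np.linalg.eigvalsh(C).min())
    if w_min <= 0:
        raise ValueError(
            f"implied {session}-session covariance is not positive definite "
            f"(min eigenvalue {w_min:.3e}) for within={spec.within_community_corr}, "
            f"between={spec.between_community_corr}, delta={spec.effect_delta_corr}"
        )


@dataclass
class SyntheticCohort:
    """Generated paired time series plus the ground truth they were drawn from."""

    spec: CohortSpec
    timeseries: dict[tuple[str, str], RoiTimeSeries]  # (subject, session) -> ts
    truth_pre: np.ndarray
    truth_post: np.ndarray

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(sorted({subj for subj, _ in self.timeseries}))

    def write(self, out_dir: str | Path) -> None:
        """One TSV per subject/session plus a JSON manifest with spec and truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (subj, sess), ts in sorted(self.timeseries.items()):
            ts.to_tsv(out / f"{subj}_{sess}_timeseries.tsv")
        manifest = {
            "spec": asdict(self.spec),
            "subjects": list(self.subject_ids),
            "sessions": ["pre", "post"],
            "truth_pre": self.truth_pre.tolist(),
            "truth_post": self.truth_post.tolist(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw paired-session region time series for every subject.

    Each session's series are i.i.d. multivariate normal draws (scaled by
    ``noise_sd``) from the session's population correlation matrix; the
    sessions differ only through the planted effect.  Deterministic for a
    given spec.
    """
    C_pre = modular_correlation(spec)
    C_post = planted_effect_correlation(spec)
    L_pre = np.linalg.cholesky(C_pre)
    L_post = np.linalg.cholesky(C_post)
    rng = np.random.default_rng(spec.seed)
    labels = spec.region_labels
    series: dict[tuple[str, str], RoiTimeSeries] = {}
    for i in range(spec.n_subjects):
        subj = f"sub{i + 1:03d}"
        for sess, L in (("pre", L_pre), ("post", L_post)):
            Z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            X = spec.noise_sd * (Z @ L.T)
            series[(subj, sess)] = RoiTimeSeries(
                data=X,
                region_labels=labels,
                subject_id=subj,
                session=sess,
                tr_seconds=spec.tr_seconds,
                provenance=("synthetic",),
            )
    return SyntheticCohort(
        spec=spec, timeseries=series, truth_pre=C_pre, truth_post=C_post
    )


def generate_pvt_log(spec: PvtSpec) -> pd.DataFrame:
    """One session's PVT trial log.

    Stimulus onsets accumulate random inter-trial intervals until the task
    duration is exceeded (uniform ITIs on the given range; a 2–10 s range
    over 5 min yields roughly duration / mean-ITI trials).  Reaction times
    are ex-Gaussian (normal(mu, sigma) + exponential(tau)); responses
    slower than 1000 ms are flagged ``too_slow`` and anticipations are
    injected as ``false_start`` at the specified rate.

    Columns: trial (1-based), onset_s, rt_ms, flag.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.iti_range_seconds
    rows = []
    onset = 0.0
    trial = 0
    while True:
        onset += lo if lo == hi else rng.uniform(lo, hi)
        if onset > spec.duration_seconds:
            break
        trial += 1
        if rng.random() < spec.false_start_rate:
            # anticipation: key pressed before/at stimulus onset
            rt = float(rng.uniform(0.0, 100.0))
            flag = "false_start"
        else:
            rt = spec.exgaussian_mu_ms + spec.exgaussian_sigma_ms * rng.standard_normal()
            if spec.exgaussian_tau_ms > 0:
                rt += rng.exponential(spec.exgaussian_tau_ms)
            rt = float(max(rt, 1.0))
            flag = "too_slow" if rt > 1000.0 else "valid"
        rows.append((trial, round(onset, 3), rt, flag))
    return pd.DataFrame(rows, columns=["trial", "onset_s", "rt_ms", "flag"])


def generate_transmittance(spec: TransmittanceSpec) -> pd.DataFrame:
    """Per-eye pre/post blue-light transmittance for a cohort.

    Pre values model an age-yellowed natural lens (normal, clipped to
    [0, 100], independently per eye); post values are the implanted lens
    class's transmittance, 68% for blue-filter lenses and 95% for clear
    ones, identical in both eyes.

    Columns: subject, eye, pre_pct, post_pct, iol_class.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_subjects):
        subj = f"sub{i + 1:03d}"
        blue = rng.random() < spec.iol_filter_fraction
        iol = "blue_filter" if blue else "clear"
        post = IOL_TRANSMITTANCE[iol]
        for eye in ("left", "right"):
            pre = float(np.clip(spec.pre_mean + spec.pre_sd * rng.standard_normal(), 0, 100))
            rows.append((subj, eye, pre, post, iol))
    return pd.DataFrame(
        rows, columns=["subject", "eye", "pre_pct", "post_pct", "iol_class"]
    )


def generate_toy_volume(
    n_regions: int,
    shape: tuple[int, int, int],
    n_timepoints: int,
    seed: int = 0,
    *,
    voxel_noise_sd: float = 0.0,
    region_ids: tuple[int, ...] | None = None,
):
    """Tiny 4D volume + label image for parcellation tests.

    Regions occupy disjoint 2x2x2 voxel blocks on a lattice; every voxel of
    a region carries that region's planted time course plus independent
    voxel noise.  ``region_ids`` may be non-contiguous (e.g. (1, 2, 4)) to
    exercise label-identity handling.  Returns (data4d, labels3d,
    planted timecourses of shape timepoints x regions).
    """
    import itertools

    if region_ids is None:
        region_ids = tuple(range(1, n_regions + 1))
    if len(region_ids) != n_regions:
        raise ValueError("region_ids length must equal n_regions")
    if len(set(region_ids)) != n_regions or min(region_ids) < 1:
        raise ValueError("region_ids must be distinct positive integers")
    block = 2
    slots = [s // block for s in shape]
    if np.prod(slots) < n_regions or min(shape) < block:
        raise ValueError(
            f"shape {shape} too small for {n_regions} disjoint {block}^3 blocks"
        )
    rng = np.random.default_rng(seed)
    courses = rng.standard_normal((n_timepoints, n_regions))
    labels = np.zeros(shape, dtype=np.int32)
    data = np.zeros(shape + (n_timepoints,), dtype=np.float64)
    positions = itertools.product(*(range(s) for s in slots))
    for r, (rid, pos) in enumerate(zip(region_ids, positions)):
        sl = tuple(slice(p * block, p * block + block) for p in pos)
        labels[sl] = rid
        data[sl] = courses[:, r]
    if voxel_noise_sd > 0:
        data[labels > 0] += rng.standard_normal(data[labels > 0].shape) * voxel_noise_sd
    return data, labels, courses
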