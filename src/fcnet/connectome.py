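"""From imaging inputs to per-subject, per-session connectivity matrices.

The temporal preprocessing chain operates on region-mean BOLD time series:

1. extract region means from a 4D image with an integer-labelled atlas,
2. discard the initial equilibration volumes (default 10),
3. regress out nuisance signals (motion parameters, WM/CSF, optionally the
   global signal) by OLS with an implicit intercept,
4. band-pass filter 0.01-0.08 Hz (zero-phase Butterworth),
5. correlate every pair of regions (Pearson) into a symmetric matrix.

Spatial preprocessing (realignment, normalisation, smoothing, CompCor
component estimation) is upstream of this package: inputs are assumed
already cleaned, with confounds supplied as tables.

Each stage records itself in the series' provenance and refuses to run
twice, so the canonical order discard -> regress -> bandpass -> correlate
cannot silently be scrambled into e.g. a double filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "extract_roi_timeseries",
    "discard_initial_volumes",
    "regress_confounds",
    "bandpass_filter",
    "motion_qc",
    "MotionQcResult",
    "compute_connectivity",
]


@dataclass
class RoiTimeSeries:
    """Region-mean BOLD signals for one subject and session.

    data is timepoints x regions; column order must be identical across a
    cohort so matrices are comparable region-by-region.
    """

    data: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""
    tr_seconds: float = 2.0
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        X = np.asarray(self.data, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("time series data must be 2-D (timepoints x regions)")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(X).any():
            raise ValueError("time series contains missing values")
        self.data = X
        self.region_labels = tuple(str(r) for r in self.region_labels)
        if len(self.region_labels) != X.shape[1]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {X.shape[1]} columns"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def _stamp(self, stage: str) -> tuple[str, ...]:
        if stage in self.provenance:
            raise ValueError(
                f"stage {stage!r} already applied to this series "
                f"(provenance: {self.provenance})"
            )
        return self.provenance + (stage,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.region_labels))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        *,
        subject_id: str = "",
        session: str = "",
        tr_seconds: float = 2.0,
    ) -> "RoiTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            data=df.to_numpy(dtype=np.float64),
            region_labels=tuple(df.columns),
            subject_id=subject_id,
            session=session,
            tr_seconds=tr_seconds,
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=np.float64)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(V) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("connectivity diagonal must be 1")
        V = np.clip((V + V.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(V, 1.0)
        self.values = V
        self.region_labels = tuple(str(r) for r in self.region_labels)
        if len(self.region_labels) != V.shape[0]:
            raise ValueError("region_labels length does not match matrix")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.region_labels)
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, *, subject_id: str = "", session: str = ""
    ) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=np.float64),
            region_labels=tuple(df.columns),
            subject_id=subject_id,
            session=session,
        )


def extract_roi_timeseries(
    image_4d,
    label_image,
    *,
    subject_id: str = "",
    session: str = "",
    tr_seconds: float = 2.0,
) -> RoiTimeSeries:
    """Average the 4D signal over each atlas label.

    Accepts nibabel spatial images or plain arrays; both must share the
    voxel grid.  Labels are positive integers (0 = background); every label
    present must contain at least one voxel, and label identity (not rank)
    names the output columns.
    """
    data4d = np.asanyarray(
        image_4d.dataobj if hasattr(image_4d, "dataobj") else image_4d,
        dtype=np.float64,
    )
    labels3d = np.asanyarray(
        label_image.dataobj if hasattr(label_image, "dataobj") else label_image
    )
    if data4d.ndim != 4:
        raise ValueError("functional image must be 4-D")
    if labels3d.shape != data4d.shape[:3]:
        raise ValueError(
            f"label grid {labels3d.shape} does not match image grid {data4d.shape[:3]}"
        )
    if not np.issubdtype(labels3d.dtype, np.integer):
        if not np.all(labels3d == np.round(labels3d)):
            raise ValueError("label image must contain integer labels")
        labels3d = labels3d.astype(np.int64)
    if labels3d.min() < 0:
        raise ValueError("labels must be non-negative (0 = background)")
    region_ids = np.unique(labels3d)
    region_ids = region_ids[region_ids > 0]
    if region_ids.size == 0:
        raise ValueError("label image contains no regions")
    n_t = data4d.shape[3]
    flat = data4d.reshape(-1, n_t)
    lab = labels3d.reshape(-1)
    cols = []
    for rid in region_ids:
        mask = lab == rid
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"region {rid} has no voxels")
        cols.append(flat[mask].mean(axis=0))
    return RoiTimeSeries(
        data=np.column_stack(cols),
        region_labels=tuple(str(int(r)) for r in region_ids),
        subject_id=subject_id,
        session=session,
        tr_seconds=tr_seconds,
        provenance=("extract",),
    )


def discard_initial_volumes(ts: RoiTimeSeries, n_discard: int = 10) -> RoiTimeSeries:
    """Drop the first ``n_discard`` timepoints (scanner signal equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard == 0:
        return ts
    if ts.n_timepoints <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} timepoints"
        )
    return replace(
        ts, data=ts.data[n_discard:], provenance=ts._stamp("discard")
    )


def regress_confounds(
    ts: RoiTimeSeries, confounds: np.ndarray | pd.DataFrame | None
) -> RoiTimeSeries:
    """Replace each region series by its OLS residual on [intercept | confounds].

    With no confounds this demeans each series.  The design (with intercept)
    must be full column rank; residuals are orthogonal to every confound.
    """
    n_t = ts.n_timepoints
    if confounds is None:
        conf = np.empty((n_t, 0))
    else:
        conf = np.asarray(
            confounds.to_numpy() if isinstance(confounds, pd.DataFrame) else confounds,
            dtype=np.float64,
        )
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != n_t:
            raise ValueError(
                f"confounds have {conf.shape[0]} rows, series has {n_t} timepoints"
            )
    X = np.column_stack([np.ones(n_t), conf])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confound design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid, provenance=ts._stamp("regress"))


def bandpass_filter(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Zero-phase band-pass (order-2 Butterworth run forward and backward).

    Retains the slow spontaneous BOLD fluctuations between ``low_hz`` and
    ``high_hz`` and removes drift and high-frequency physiological noise.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz at TR {ts.tr_seconds} s)"
        )
    sos = signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=filtered, provenance=ts._stamp("bandpass"))


@dataclass(frozen=True)
class MotionQcResult:
    passed: bool
    max_translation_mm: tuple[float, float, float]
    max_rotation_deg: tuple[float, float, float]


def motion_qc(
    motion_params: np.ndarray | pd.DataFrame,
    *,
    translation_mm: float = 3.0,
    rotation_deg: float = 3.0,
) -> MotionQcResult:
    """Flag excessive head motion: fail iff any |translation| > 3 mm or |rotation| > 3 deg.

    Expects timepoints x 6 (three translations in mm, three rotations in
    degrees).  The comparison is a strict exceedance, so exactly 3.0 passes.
    """
    M = np.asarray(
        motion_params.to_numpy()
        if isinstance(motion_params, pd.DataFrame)
        else motion_params,
        dtype=np.float64,
    )
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion parameters must be timepoints x 6")
    maxima = np.abs(M).max(axis=0)
    trans, rot = maxima[:3], maxima[3:]
    passed = bool((trans <= translation_mm).all() and (rot <= rotation_deg).all())
    return MotionQcResult(
        passed=passed,
        max_translation_mm=tuple(trans),
        max_rotation_deg=tuple(rot),
    )


def compute_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of region series."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.data.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = [ts.region_labels[i] for i in dead]
        raise ValueError(f"zero-variance region(s): {names}")
    C = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(
        values=np.clip(C, -1.0, 1.0),
        region_labels=ts.region_labels,
        subject_id=ts.subject_id,
        session=ts.session,
    )
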