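"""Post-extraction BOLD signal cleaning and motion quality control.

The pipeline starts from parcellated ROI time series (one T x R matrix
per subject) and six rigid-body motion parameters per frame.  The steps
here mirror the standard resting-state cleanup applied after image-level
preprocessing: dropping initial volumes, nuisance regression (Friston-24
motion expansion, optional global signal), band-pass filtering to the
low-frequency band, and exclusion of high-motion subjects by mean
framewise displacement.

Default order is discard -> nuisance regression -> band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "RoiTimeSeries",
    "MotionTrace",
    "discard_initial",
    "friston24",
    "compute_fd",
    "qc_exclude",
    "nuisance_regress",
    "bandpass",
    "BandpassFilter",
    "DEFAULT_HEAD_RADIUS_MM",
    "DEFAULT_FD_THRESHOLD_MM",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.2


@dataclass
class RoiTimeSeries:
    """One subject's T x R signal matrix with its sampling interval."""

    data: np.ndarray
    tr: float
    subject_id: str = ""
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time x ROI matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(data, self.tr, self.subject_id, self.roi_labels)


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame.

    Columns 0-2 are translations in mm, columns 3-5 rotations in
    radians.  Framewise displacement converts rotations to arc length on
    a sphere of ``head_radius`` mm.
    """

    params: np.ndarray
    subject_id: str = ""
    head_radius: float = DEFAULT_HEAD_RADIUS_MM
    fd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be a time x 6 matrix")
        if self.params.shape[0] < 2:
            raise ValueError("need at least 2 frames of motion")
        self.fd = compute_fd(self.params, self.head_radius)

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


def discard_initial(ts: RoiTimeSeries, n_discard: int = 10) -> RoiTimeSeries:
    """Drop the first ``n_discard`` volumes (scanner equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes"
        )
    if n_discard == 0:
        return ts
    return ts.with_data(ts.data[n_discard:])


def friston24(motion: MotionTrace | np.ndarray) -> np.ndarray:
    """24-regressor motion expansion: [p(t), p(t-1), p(t)^2, p(t-1)^2].

    Lagged columns are zero-padded at the first frame.
    """
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion params must be a time x 6 matrix")
    lag = np.zeros_like(params)
    lag[1:] = params[:-1]
    return np.hstack([params, lag, params**2, lag**2])


def compute_fd(
    params: MotionTrace | np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences of
    the translations plus ``head_radius`` times those of the rotations.

    ``fd[0]`` is 0 by convention.
    """
    if head_radius <= 0:
        raise ValueError("head_radius must be positive (mm)")
    p = params.params if isinstance(params, MotionTrace) else np.asarray(params, float)
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters contain non-finite values")
    d = np.abs(np.diff(p, axis=0))
    fd = np.zeros(p.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def qc_exclude(
    cohort: Iterable[MotionTrace] | Mapping[str, MotionTrace],
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
) -> pd.DataFrame:
    """Partition subjects by the mean-FD motion criterion.

    A subject is excluded iff mean FD is *strictly* greater than
    ``threshold`` (default 0.2 mm).  Returns one row per subject with
    columns ``subject_id``, ``mean_fd``, ``kept``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (mm)")
    if isinstance(cohort, Mapping):
        items = [(sid, m) for sid, m in cohort.items()]
    else:
        items = [(m.subject_id or str(i), m) for i, m in enumerate(cohort)]
    rows = [
        {"subject_id": sid, "mean_fd": m.mean_fd, "kept": m.mean_fd <= threshold}
        for sid, m in items
    ]
    return pd.DataFrame(rows, columns=["subject_id", "mean_fd", "kept"])


def nuisance_regress(
    ts: RoiTimeSeries, regressors: np.ndarray | None
) -> RoiTimeSeries:
    """Replace each ROI signal by its OLS residual on [1 | regressors].

    The intercept is always included, so the output columns are
    mean-centred.  Raises on a rank-deficient design, naming the
    offending columns.
    """
    T = ts.n_volumes
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        X = np.ones((T, 1))
    else:
        R = np.asarray(regressors, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[0] != T:
            raise ValueError(
                f"regressors have {R.shape[0]} rows but series has {T}"
            )
        X = np.column_stack([np.ones(T), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(
            f"rank-deficient nuisance design (rank {rank} < {X.shape[1]}); "
            f"collinear columns (0 = intercept): {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ts.with_data(ts.data - X @ beta)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Columns whose removal leaves matrix rank unchanged."""
    full = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == full:
            out.append(j)
    return out


def bandpass(
    ts: RoiTimeSeries, low: float = 0.01, high: float = 0.10
) -> RoiTimeSeries:
    """Ideal (boxcar) frequency-domain band-pass filter.

    Discrete Fourier coefficients with frequency outside [low, high] Hz
    are zeroed, including the 0-frequency mean, and the series is
    inverse-transformed.  Exactly reproducible; no filter-order choice.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high > nyquist + 1e-12:
        raise ValueError(
            f"high={high} Hz exceeds the Nyquist frequency "
            f"{nyquist:.6g} Hz for tr={ts.tr} s"
        )
    spec = np.fft.rfft(ts.data, axis=0)
    freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec[~keep] = 0.0
    return ts.with_data(np.fft.irfft(spec, n=ts.n_volumes, axis=0))


class BandpassFilter(TransformerMixin, BaseEstimator):
    """scikit-learn transformer form of :func:`bandpass`.

    Operates column-wise on a T x R array; ``tr`` is the sampling
    interval in seconds.
    """

    def __init__(self, low: float = 0.01, high: float = 0.10, tr: float = 2.0):
        self.low = low
        self.high = high
        self.tr = tr

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        ts = RoiTimeSeries(X, tr=self.tr)
        return bandpass(ts, self.low, self.high).data
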