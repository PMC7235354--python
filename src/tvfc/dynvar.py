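"""Temporal variability of windowed functional connectivity.

The statistic: split a T x R ROI time series into non-overlapping
windows of length l, compute a Pearson FC matrix per window, and
measure how much an FC pattern changes across windows as

    V = 1 - mean over window pairs (i < j) of corr(F_i, F_j)

where F_i is the vectorised FC pattern of window i.  Three pattern
levels are computed:

* regional: F_i = row k of the window-i FC matrix with the diagonal
  (self-correlation) entry removed, one value per ROI;
* intra-network: F_i = strict upper triangle of the network's FC
  sub-block, one value per network (undefined for networks of fewer
  than 3 ROIs);
* inter-network: F_i = the full cross-block between two networks, one
  value per unordered network pair.

Each defined value lies in [0, 2]: 0 for perfectly stable patterns, 2
for perfectly anticorrelated ones.  To remove dependence on the window
grid, the statistic is averaged over window lengths l = 21..30 volumes
and, for each l, over all l-1 start offsets s = 1..l-1 (trailing
partial windows discarded), with equal weight per (l, s) segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .parcellation import Parcellation
from .preprocess import RoiTimeSeries

__all__ = [
    "WindowScheme",
    "WindowFcStack",
    "VariabilityProfile",
    "segment_windows",
    "window_fc",
    "regional_variability",
    "intra_network_variability",
    "inter_network_variability",
    "multiscale_variability",
    "TemporalVariabilityExtractor",
    "profile_to_row",
    "feature_names",
]

DEFAULT_LENGTHS = tuple(range(21, 31))

# a segmentation-level value is dropped when more than this fraction of
# window pairs had undefined correlations
MAX_SKIPPED_PAIR_FRACTION = 0.5


@dataclass(frozen=True)
class WindowScheme:
    """Multi-scale window grid: every start offset s = 1..l-1 for each
    window length l (volumes)."""

    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    min_windows: int = 2

    def __post_init__(self) -> None:
        if any(l < 2 for l in self.lengths):
            raise ValueError("window lengths must be >= 2 volumes")
        if self.min_windows < 2:
            raise ValueError("min_windows must be >= 2")

    def segmentations(self, T: int) -> list[tuple[int, int]]:
        """All (l, s) pairs whose segmentation of T volumes retains at
        least ``min_windows`` windows."""
        out = []
        for l in self.lengths:
            for s in range(1, l):
                if (T - s + 1) // l >= self.min_windows:
                    out.append((l, s))
        return out


@dataclass
class WindowFcStack:
    """Per-window FC matrices for one (length, offset) segmentation."""

    windows: list[tuple[int, int]]  # half-open 0-based [start, end)
    fc: np.ndarray  # (num, R, R)

    @property
    def num(self) -> int:
        return len(self.windows)


@dataclass
class VariabilityProfile:
    """Per-subject multi-scale variability values.

    Undefined values (degenerate networks, all-pairs-skipped
    segmentations) are NaN, never silently 0.
    """

    regional: pd.Series  # index = ROI labels
    intra: pd.Series  # index = network names
    inter: pd.Series  # index = "netA__netB", lexicographic pairs
    n_segmentations_used: int


def segment_windows(T: int, l: int, s: int) -> list[tuple[int, int]]:
    """Non-overlapping windows of length ``l`` starting at the ``s``-th
    volume (1-based), trailing partial window discarded.

    Returns half-open 0-based (start, end) intervals; the number of
    windows is floor((T - s + 1) / l).
    """
    if l < 2:
        raise ValueError("window length must be >= 2")
    if not (1 <= s <= l - 1):
        raise ValueError(f"start offset s={s} must lie in 1..{l - 1}")
    num = (T - s + 1) // l
    return [(s - 1 + i * l, s - 1 + (i + 1) * l) for i in range(num)]


def window_fc(ts: RoiTimeSeries | np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Pearson correlation matrix of the ROI signals within a window.

    ROIs constant within the window get NaN rows/columns (their
    correlation is undefined); the diagonal is 1 where defined.
    """
    data = ts.data if isinstance(ts, RoiTimeSeries) else np.asarray(ts, float)
    a, b = window
    if b - a < 3:
        raise ValueError("window length must be >= 3 frames")
    if a < 0 or b > data.shape[0]:
        raise ValueError(f"window {window} outside series of length {data.shape[0]}")
    seg = data[a:b]
    centred = seg - seg.mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centred / np.where(norms > 0, norms, 1.0), np.nan)
        fc = z.T @ z
    fc = np.clip(fc, -1.0, 1.0)
    defined = norms > 0
    np.fill_diagonal(fc, np.where(defined, 1.0, np.nan))
    fc[~defined, :] = np.nan
    fc[:, ~defined] = np.nan
    return fc


def _fc_stack(data: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    return np.stack([window_fc(data, w) for w in windows])


def _mean_pairwise_corr(V: np.ndarray) -> tuple[float, int, int]:
    """Mean Pearson correlation over all unordered pairs of rows of V
    (num x p), skipping pairs involving invalid rows (non-finite
    entries or zero variance).

    Returns (mean_corr, n_pairs_used, n_pairs_total); mean is NaN when
    no pair is usable.
    """
    num, p = V.shape
    total = num * (num - 1) // 2
    valid = np.isfinite(V).all(axis=1)
    Vv = V[valid]
    centred = Vv - Vv.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    ok = norms > 0
    Z = centred[ok] / norms[ok][:, None]
    k = Z.shape[0]
    used = k * (k - 1) // 2
    if used == 0:
        return float("nan"), 0, total
    # cosine of unit vectors; clip the odd ulp excursion beyond +/-1
    C = np.clip(Z @ Z.T, -1.0, 1.0)
    iu = np.triu_indices(k, 1)
    return float(C[iu].mean()), used, total


def _variability_from_vectors(V: np.ndarray) -> float:
    """V = 1 - mean pairwise correlation; NaN if more than half the
    window pairs were skipped."""
    mean_corr, used, total = _mean_pairwise_corr(V)
    if total == 0 or used < total * (1.0 - MAX_SKIPPED_PAIR_FRACTION):
        return float("nan")
    return 1.0 - mean_corr


def regional_variability(stack: WindowFcStack | np.ndarray, k: int) -> float:
    """Variability of ROI k's whole-brain FC row (diagonal removed)."""
    fc = stack.fc if isinstance(stack, WindowFcStack) else np.asarray(stack)
    R = fc.shape[1]
    cols = np.arange(R) != k
    return _variability_from_vectors(fc[:, k, cols])


def intra_network_variability(
    stack: WindowFcStack | np.ndarray, members: Sequence[int]
) -> float:
    """Variability of the within-network FC block (strict upper
    triangle, row-major order).  NaN for networks of < 3 ROIs."""
    fc = stack.fc if isinstance(stack, WindowFcStack) else np.asarray(stack)
    idx = np.asarray(members, dtype=int)
    if idx.size < 3:
        return float("nan")
    block = fc[:, idx[:, None], idx[None, :]]
    iu = np.triu_indices(idx.size, 1)
    return _variability_from_vectors(block[:, iu[0], iu[1]])


def inter_network_variability(
    stack: WindowFcStack | np.ndarray,
    members_m: Sequence[int],
    members_n: Sequence[int],
) -> float:
    """Variability of the cross-network FC block (full |m| x |n| block,
    row-major).  Symmetric in (m, n)."""
    fc = stack.fc if isinstance(stack, WindowFcStack) else np.asarray(stack)
    mi = np.asarray(members_m, dtype=int)
    ni = np.asarray(members_n, dtype=int)
    if np.intersect1d(mi, ni).size:
        raise ValueError("networks overlap; members must be disjoint")
    if mi.size * ni.size < 2:
        return float("nan")
    block = fc[:, mi[:, None], ni[None, :]].reshape(fc.shape[0], -1)
    return _variability_from_vectors(block)


def _segmentation_profile(
    fc: np.ndarray,
    member_sets: list[np.ndarray],
    pair_indices: list[tuple[int, int]],
    fisher_z: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All three statistic levels for one window stack.

    Regional values are computed batched across ROIs; intra/inter fall
    through the per-block helpers.
    """
    num, R, _ = fc.shape
    if fisher_z:
        fc = np.arctanh(np.clip(fc, -1.0 + 1e-12, 1.0 - 1e-12))

    # regional, batched: F has shape (R, num, R-1)
    off = ~np.eye(R, dtype=bool)
    rows = fc.transpose(1, 0, 2)  # (R, num, R)
    F = rows[:, :, :].reshape(R, num, R)
    F = np.stack([F[k][:, off[k]] for k in range(R)])
    regional = np.empty(R)
    total = num * (num - 1) // 2
    valid = np.isfinite(F).all(axis=2)  # (R, num)
    centred = F - F.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centred, axis=2)
    ok = valid & (norms > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(ok[:, :, None], centred / np.where(norms > 0, norms, 1.0)[:, :, None], 0.0)
    C = np.clip(Z @ Z.transpose(0, 2, 1), -1.0, 1.0)  # (R, num, num)
    iu = np.triu_indices(num, 1)
    pair_ok = ok[:, iu[0]] & ok[:, iu[1]]  # (R, n_pairs)
    sums = np.where(pair_ok, C[:, iu[0], iu[1]], 0.0).sum(axis=1)
    used = pair_ok.sum(axis=1)
    min_used = total * (1.0 - MAX_SKIPPED_PAIR_FRACTION)
    with np.errstate(invalid="ignore"):
        regional = np.where(used >= np.maximum(min_used, 1), 1.0 - sums / np.maximum(used, 1), np.nan)

    intra = np.array([intra_network_variability(fc, m) for m in member_sets])
    inter = np.array(
        [inter_network_variability(fc, member_sets[a], member_sets[b]) for a, b in pair_indices]
    )
    return regional, intra, inter


def _subject_profile(
    data: np.ndarray,
    parcellation: Parcellation,
    scheme: WindowScheme,
    fisher_z: bool = False,
) -> VariabilityProfile:
    T, R = data.shape
    if R != parcellation.n_rois:
        raise ValueError(
            f"series has {R} ROIs but parcellation declares {parcellation.n_rois}"
        )
    net_names = sorted(parcellation.network_names)
    member_sets = [parcellation.members(n) for n in net_names]
    pair_names = parcellation.network_pairs()
    pair_indices = [(net_names.index(a), net_names.index(b)) for a, b in pair_names]

    segs = scheme.segmentations(T)
    if not segs:
        raise ValueError(
            f"no window segmentation of {T} volumes retains at least "
            f"{scheme.min_windows} windows for lengths {scheme.lengths}"
        )
    reg_acc = np.zeros((len(segs), R))
    intra_acc = np.zeros((len(segs), len(net_names)))
    inter_acc = np.zeros((len(segs), len(pair_names)))
    for i, (l, s) in enumerate(segs):
        windows = segment_windows(T, l, s)
        fc = _fc_stack(data, windows)
        reg_acc[i], intra_acc[i], inter_acc[i] = _segmentation_profile(
            fc, member_sets, pair_indices, fisher_z
        )
    with np.errstate(invalid="ignore"):
        regional = _nanmean_cols(reg_acc)
        intra = _nanmean_cols(intra_acc)
        inter = _nanmean_cols(inter_acc)
    return VariabilityProfile(
        regional=pd.Series(regional, index=list(parcellation.roi_labels)),
        intra=pd.Series(intra, index=net_names),
        inter=pd.Series(inter, index=[f"{a}__{b}" for a, b in pair_names]),
        n_segmentations_used=len(segs),
    )


def _nanmean_cols(a: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (no warning) for all-NaN columns."""
    mask = np.isfinite(a)
    counts = mask.sum(axis=0)
    sums = np.where(mask, a, 0.0).sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def multiscale_variability(
    ts: RoiTimeSeries | np.ndarray,
    parcellation: Parcellation,
    scheme: WindowScheme | None = None,
    fisher_z: bool = False,
) -> VariabilityProfile:
    """Multi-scale averaged variability profile for one subject.

    All (l, s) segmentations retained by ``scheme`` are computed and
    averaged with equal weight (245 segmentations for T=240 with the
    default 21..30 grid).
    """
    data = ts.data if isinstance(ts, RoiTimeSeries) else np.asarray(ts, float)
    return _subject_profile(data, parcellation, scheme or WindowScheme(), fisher_z)


def feature_names(parcellation: Parcellation) -> list[str]:
    """Flattened feature column order: regional, intra, inter."""
    names = [f"regional_{lab}" for lab in parcellation.roi_labels]
    names += [f"intra_{n}" for n in sorted(parcellation.network_names)]
    names += [f"inter_{a}__{b}" for a, b in parcellation.network_pairs()]
    return names


def profile_to_row(profile: VariabilityProfile) -> np.ndarray:
    return np.concatenate(
        [profile.regional.values, profile.intra.values, profile.inter.values]
    )


class TemporalVariabilityExtractor(TransformerMixin, BaseEstimator):
    """Extract multi-scale FC-variability features per subject.

    Each sample is one subject's T x R ROI time-series matrix; the
    transform output is an (n_subjects, n_features) array with columns
    ``regional_<roi>``, ``intra_<network>`` and
    ``inter_<netA>__<netB>`` (network pairs in lexicographic order).
    Undefined features (for example the intra-network value of a 2-ROI
    network) are NaN.

    Parameters
    ----------
    parcellation : Parcellation
        ROI -> network assignment; its ROI count must match R.
    lengths : tuple of int, default 21..30
        Window lengths in volumes; all start offsets 1..l-1 are used
        per length and averaged with equal weight.
    min_windows : int, default 2
        Segmentations retaining fewer windows are skipped.
    fisher_z : bool, default False
        Apply Fisher's z to FC values before the across-window
        correlation (sensitivity analysis; the statistic as defined
        operates on raw correlations).
    levels : tuple of str
        Which statistic levels to emit, any of "regional", "intra",
        "inter".
    """

    def __init__(
        self,
        parcellation: Parcellation,
        lengths: tuple[int, ...] = DEFAULT_LENGTHS,
        min_windows: int = 2,
        fisher_z: bool = False,
        levels: tuple[str, ...] = ("regional", "intra", "inter"),
    ):
        self.parcellation = parcellation
        self.lengths = lengths
        self.min_windows = min_windows
        self.fisher_z = fisher_z
        self.levels = levels

    def _scheme(self) -> WindowScheme:
        return WindowScheme(tuple(self.lengths), self.min_windows)

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X[0].shape[1]
        self.feature_names_out_ = np.asarray(self._names(), dtype=object)
        self.n_segmentations_: dict[int, int] = {}
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        X = self._validate(X)
        scheme = self._scheme()
        rows = []
        for data in X:
            prof = _subject_profile(data, self.parcellation, scheme, self.fisher_z)
            self.n_segmentations_[data.shape[0]] = prof.n_segmentations_used
            parts = []
            if "regional" in self.levels:
                parts.append(prof.regional.values)
            if "intra" in self.levels:
                parts.append(prof.intra.values)
            if "inter" in self.levels:
                parts.append(prof.inter.values)
            rows.append(np.concatenate(parts))
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_

    def _names(self) -> list[str]:
        p = self.parcellation
        names: list[str] = []
        if "regional" in self.levels:
            names += [f"regional_{lab}" for lab in p.roi_labels]
        if "intra" in self.levels:
            names += [f"intra_{n}" for n in sorted(p.network_names)]
        if "inter" in self.levels:
            names += [f"inter_{a}__{b}" for a, b in p.network_pairs()]
        return names

    def _validate(self, X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            mats = [X[i] for i in range(X.shape[0])]
        else:
            mats = [m.data if isinstance(m, RoiTimeSeries) else np.asarray(m, float) for m in X]
        if not mats:
            raise ValueError("need at least one subject")
        R = self.parcellation.n_rois
        for i, m in enumerate(mats):
            if m.ndim != 2:
                raise ValueError(f"subject {i}: expected a 2-D time x ROI matrix")
            if m.shape[1] != R:
                raise ValueError(
                    f"subject {i}: {m.shape[1]} ROIs != parcellation's {R}"
                )
            if not np.all(np.isfinite(m)):
                raise ValueError(f"subject {i}: non-finite values in series")
        return mats
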