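"""Synthetic resting-state cohorts with planted FC dynamics.

Each subject's ROI series is drawn from a zero-mean multivariate
Gaussian whose correlation structure alternates between two regimes:

    Sigma(t) = Q(w(t) * a) Sigma_A Q(w(t) * a)^T,   Q(x) = expm(x * S)

where w(t) is a square wave (period ``regime_period`` volumes,
sinusoidal optional), ``a`` the group's modulation amplitude in
[0, 1], and S a fixed random skew-symmetric generator acting only on
the ``modulated_rois`` coordinates (equal-angle planes, a half turn
at a = 1).  The second regime is thus a rotation of the base covariance
within the modulated subspace: entries among unmodulated ROIs are
untouched (a = 0 there), the planted FC-pattern change grows
monotonically with the rotation angle, the pattern magnitude is
preserved along the whole path (no amplitude at which the modulated
ROIs' connectivity degenerates), and every Sigma(t) is positive
definite by congruence for any amplitude.  White measurement noise of
sd ``noise_sd`` is added.

Motion traces are seeded random walks rescaled so each subject hits a
drawn target mean framewise displacement exactly.  Covariates
(age, sex, education) and clinical scores are drawn per subject; one
named score is tied to the subject's true modulation amplitude with a
controllable target Spearman correlation.

The defaults mirror the acquisition the pipeline expects: R=116 ROIs,
T=250 volumes at TR=2 s, three groups of 66/53/66 subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import MotionTrace, RoiTimeSeries

__all__ = ["SimulationSpec", "CohortData", "simulate_subject", "simulate_cohort", "write_cohort"]

PATIENT_SCORES = ("illness_duration", "cpz_equiv", "saps", "sans", "hamd", "ymrs")
COGNITIVE_SCORES = ("wais_i", "wais_ds")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic cohort; output is a pure
    function of this object (including ``seed``)."""

    n_rois: int = 116
    n_volumes: int = 250
    tr: float = 2.0
    n_per_group: tuple[int, int, int] = (66, 53, 66)
    group_labels: tuple[str, str, str] = ("HC", "BD", "SZ")
    group_amplitudes: tuple[float, float, float] = (0.0, 0.3, 0.6)
    mean_offdiag: float = 0.2
    modulated_rois: tuple[int, ...] | None = None
    regime_period: int = 40
    square_wave: bool = True
    noise_sd: float = 0.2
    mean_fd_loc: float = 0.08
    mean_fd_scale: float = 0.04
    clinical_score: str = "sans"
    clinical_score_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2 or self.n_volumes < 2:
            raise ValueError("need n_rois >= 2 and n_volumes >= 2")
        if self.regime_period < 2:
            raise ValueError("regime_period must be >= 2 volumes")
        for a in self.group_amplitudes:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"modulation amplitude a={a} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolved_modulated(self) -> np.ndarray:
        if self.modulated_rois is not None:
            idx = np.asarray(self.modulated_rois, dtype=int)
        elif self.n_rois == 116:
            # caudate, putamen, pallidum, thalamus in AAL order
            idx = np.arange(70, 78)
        else:
            idx = np.arange(max(2, self.n_rois // 5))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_rois):
            raise ValueError("modulated_rois outside 0..n_rois-1")
        return idx


@dataclass
class CohortData:
    spec: SimulationSpec
    series: list[RoiTimeSeries]
    motion: list[MotionTrace]
    manifest: pd.DataFrame  # subject_id, group, age, sex, education, scores
    truth: pd.DataFrame  # subject_id, amplitude


def _random_correlation(rng: np.random.Generator, R: int, mean_offdiag: float) -> np.ndarray:
    """Random correlation matrix with approximately the requested mean
    off-diagonal value: a Wishart-style correlation shrunk toward the
    constant-correlation matrix (both PD, so the blend is PD)."""
    B = rng.standard_normal((R, 2 * R))
    S = B @ B.T / (2 * R)
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    rho = float(np.clip(mean_offdiag, 0.0, 0.8))
    J = np.full((R, R), 1.0)
    out = (1 - rho) * C + rho * J
    np.fill_diagonal(out, 1.0)
    return out


def _rotation_generator(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random skew-symmetric k x k generator S = pi * U J U^T with
    randomly oriented planes that all rotate by the same angle pi * a
    under expm(a * S): the amplitude has one homogeneous meaning across
    the whole modulated subspace, up to a half turn at a = 1.  With k
    odd one direction stays fixed; with k = 1 there is no plane to
    rotate and the regime never changes."""
    G = rng.standard_normal((k, k))
    U, _ = np.linalg.qr(G)
    J = np.zeros((k, k))
    for i in range(0, k - 1, 2):
        J[i, i + 1], J[i + 1, i] = 1.0, -1.0
    return math.pi * U @ J @ U.T


def _regime_covariances(spec: SimulationSpec, rng: np.random.Generator):
    """Base and regime-on covariance Cholesky factors per group
    amplitude; the on-regime rotates the modulated subspace by an
    angle proportional to the amplitude."""
    from scipy.linalg import expm

    R = spec.n_rois
    sigma_a = _random_correlation(rng, R, spec.mean_offdiag)
    idx = spec.resolved_modulated()
    S = _rotation_generator(rng, idx.size)
    if np.linalg.eigvalsh(sigma_a).min() <= 0:
        raise ValueError("base covariance is not positive definite")
    per_amp = {}
    for a in sorted(set(spec.group_amplitudes)):
        Q = np.eye(R)
        Q[np.ix_(idx, idx)] = expm(a * S)
        sig1 = Q @ sigma_a @ Q.T
        if np.linalg.eigvalsh(sig1).min() <= 0:  # numerical safety net
            raise ValueError(
                f"rotated covariance is not positive definite at amplitude a={a}"
            )
        per_amp[a] = (np.linalg.cholesky(sigma_a), np.linalg.cholesky(sig1))
    return per_amp


def _regime_weight(spec: SimulationSpec, t: np.ndarray) -> np.ndarray:
    phase = (t % spec.regime_period) / spec.regime_period
    if spec.square_wave:
        return (phase >= 0.5).astype(float)
    return 0.5 * (1.0 + np.sin(2 * math.pi * phase))


def _simulate_series(
    spec: SimulationSpec,
    amplitude: float,
    chols,
    rng: np.random.Generator,
) -> np.ndarray:
    T, R = spec.n_volumes, spec.n_rois
    chol0, chol1 = chols
    w = _regime_weight(spec, np.arange(T))
    eps = rng.standard_normal((T, R))
    if spec.square_wave:
        x = np.empty((T, R))
        on = w >= 0.5
        x[~on] = eps[~on] @ chol0.T
        x[on] = eps[on] @ chol1.T
    else:
        # continuous blend: per-frame covariance, cached by weight value
        sigma0 = chol0 @ chol0.T
        sigma1 = chol1 @ chol1.T
        x = np.empty((T, R))
        cache: dict[float, np.ndarray] = {}
        for t in range(T):
            key = round(float(w[t]), 6)
            if key not in cache:
                cache[key] = np.linalg.cholesky((1 - key) * sigma0 + key * sigma1)
            x[t] = cache[key] @ eps[t]
    return x + spec.noise_sd * rng.standard_normal((T, R))


def _simulate_motion(
    spec: SimulationSpec, rng: np.random.Generator, target_mean_fd: float | None = None
) -> MotionTrace:
    T = spec.n_volumes
    if target_mean_fd is None:
        target_mean_fd = abs(rng.normal(spec.mean_fd_loc, spec.mean_fd_scale))
        target_mean_fd = float(np.clip(target_mean_fd, 0.005, 0.6))
    # rotations drawn 50x smaller so translations and rotation arc
    # length contribute comparably to FD
    steps = np.column_stack(
        [rng.standard_normal((T - 1, 3)), rng.standard_normal((T - 1, 3)) / 50.0]
    )
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    trace = MotionTrace(params)
    if trace.mean_fd > 0:
        params = params * (target_mean_fd / trace.mean_fd)  # FD is linear in scale
        trace = MotionTrace(params)
    return trace


def simulate_subject(
    spec: SimulationSpec,
    group_index: int,
    subject_seed: int,
    target_mean_fd: float | None = None,
    _chols=None,
) -> tuple[RoiTimeSeries, MotionTrace]:
    """One subject's series and motion trace.

    Deterministic in (spec, group_index, subject_seed).  The regime
    covariances are shared across the cohort and derived from
    ``spec.seed``; they can be precomputed and passed as ``_chols``.
    """
    a = spec.group_amplitudes[group_index]
    if _chols is None:
        cov_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
        _chols = _regime_covariances(spec, cov_rng)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    data = _simulate_series(spec, a, _chols[a], rng)
    motion = _simulate_motion(spec, rng, target_mean_fd)
    ts = RoiTimeSeries(data, tr=spec.tr)
    return ts, motion


def _scores_for(
    spec: SimulationSpec,
    group: str,
    amplitude_z: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    rho = float(np.clip(spec.clinical_score_rho, -0.99, 0.99))
    # bivariate-normal Pearson r giving the target Spearman rho
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    latent = r * amplitude_z + math.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal()
    is_patient = group != spec.group_labels[0]
    scores: dict[str, float] = {}
    for name in PATIENT_SCORES:
        if not is_patient:
            scores[name] = float("nan")
            continue
        base = {
            "illness_duration": max(0.3, rng.normal(8, 5)),
            "cpz_equiv": max(0.0, rng.normal(300, 150)),
            "saps": max(0.0, rng.normal(15, 8)),
            "sans": max(0.0, rng.normal(20, 10)),
            "hamd": max(0.0, rng.normal(6, 4)),
            "ymrs": max(0.0, rng.normal(5, 4)),
        }[name]
        scores[name] = float(base)
    if is_patient and spec.clinical_score in scores:
        scores[spec.clinical_score] = float(max(0.0, 20.0 + 10.0 * latent))
    for name in COGNITIVE_SCORES:
        scores[name] = float(rng.normal(100, 15) - 5.0 * latent)
    return scores


def simulate_cohort(spec: SimulationSpec, outdir: str | Path | None = None) -> CohortData:
    """Generate the full cohort; optionally write it as TSV files.

    The linked clinical score is calibrated through a latent Gaussian
    so its sample Spearman correlation with the subjects' true
    amplitudes approaches ``clinical_score_rho``.
    """
    cov_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
    chols = _regime_covariances(spec, cov_rng)
    meta_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 88]))

    amps = np.repeat(spec.group_amplitudes, spec.n_per_group)
    amp_sd = float(np.std(amps))
    amp_mean = float(np.mean(amps))

    series: list[RoiTimeSeries] = []
    motions: list[MotionTrace] = []
    man_rows = []
    truth_rows = []
    sid = 0
    for gi, (label, n) in enumerate(zip(spec.group_labels, spec.n_per_group)):
        for _ in range(n):
            subject_id = f"sub-{sid + 1:03d}"
            ts, motion = simulate_subject(spec, gi, subject_seed=1000 + sid, _chols=chols)
            ts.subject_id = subject_id
            motion.subject_id = subject_id
            a = spec.group_amplitudes[gi]
            amp_z = 0.0 if amp_sd == 0 else (a - amp_mean) / amp_sd
            # small jitter breaks rank ties among equal group amplitudes
            amp_z += 1e-3 * meta_rng.standard_normal()
            row = {
                "subject_id": subject_id,
                "group": label,
                "age": float(np.clip(meta_rng.normal(33, 9), 18, 60)),
                "sex": "F" if meta_rng.random() < 0.5 else "M",
                "education": float(np.clip(meta_rng.normal(12.5, 3), 6, 20)),
            }
            row.update(_scores_for(spec, label, amp_z, meta_rng))
            man_rows.append(row)
            truth_rows.append({"subject_id": subject_id, "amplitude": a})
            series.append(ts)
            motions.append(motion)
            sid += 1
    manifest = pd.DataFrame(man_rows)
    truth = pd.DataFrame(truth_rows)
    cohort = CohortData(spec, series, motions, manifest, truth)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: CohortData, outdir: str | Path) -> None:
    """Write per-subject series/motion TSVs plus manifest and
    ground-truth tables in the dialects the pipeline reads."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {outdir}: {e}") from e
    R = cohort.spec.n_rois
    labels = [f"roi_{i + 1:03d}" for i in range(R)]
    for ts, motion in zip(cohort.series, cohort.motion):
        pd.DataFrame(ts.data, columns=labels).to_csv(
            outdir / f"{ts.subject_id}_series.tsv", sep="\t", index=False, float_format="%.8g"
        )
        pd.DataFrame(
            motion.params, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).to_csv(
            outdir / f"{motion.subject_id}_motion.tsv", sep="\t", index=False, float_format="%.8g"
        )
    cohort.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False, float_format="%.8g")
    cohort.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.8g")
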