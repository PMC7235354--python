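"""End-to-end orchestration: simulate/load -> QC -> preprocess ->
variability features -> group statistics.

A run is described by a single declarative :class:`RunConfig` whose
defaults are the standard analysis settings (discard 10 volumes,
Friston-24 nuisance regression, 0.01-0.10 Hz band-pass, no GSR, mean-FD
exclusion at 0.2 mm, 21..30-volume window grid, ANCOVA gate at 0.05
with Bonferroni-corrected post-hoc contrasts).  Re-running an identical
config reproduces byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynvar import TemporalVariabilityExtractor, DEFAULT_LENGTHS
from .parcellation import Parcellation, default_parcellation, load_parcellation
from .preprocess import (
    DEFAULT_FD_THRESHOLD_MM,
    MotionTrace,
    RoiTimeSeries,
    bandpass,
    discard_initial,
    friston24,
    nuisance_regress,
    qc_exclude,
)
from .stats import DEFAULT_COVARIATES, clinical_correlations, group_comparison
from .synthetic import (
    PATIENT_SCORES,
    COGNITIVE_SCORES,
    CohortData,
    SimulationSpec,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    # inputs: either a directory of TSVs with a manifest, or a simulation
    data_dir: str | None = None
    parcellation_path: str | None = None  # None -> packaged AAL-116 table
    simulate: SimulationSpec | None = None
    # preprocessing
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.10)
    gsr: bool = False
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM
    # window scheme
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    min_windows: int = 2
    fisher_z: bool = False
    # statistics
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    gate_alpha: float = 0.05
    alpha: float = 0.05
    fdr: bool = False
    include_subjects: tuple[str, ...] | None = None  # matched-subset filter
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(**{k: _tuplify(v) for k, v in d.items()})
        if sim is not None:
            cfg.simulate = SimulationSpec(**{k: _tuplify(v) for k, v in sim.items()})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def load_cohort_dir(data_dir: str | Path, tr: float = 2.0) -> CohortData:
    """Read a cohort written in the pipeline's TSV dialects."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    series, motions = [], []
    for sid in manifest["subject_id"]:
        sdf = pd.read_csv(data_dir / f"{sid}_series.tsv", sep="\t")
        mdf = pd.read_csv(data_dir / f"{sid}_motion.tsv", sep="\t")
        series.append(
            RoiTimeSeries(sdf.values, tr=tr, subject_id=sid, roi_labels=tuple(sdf.columns))
        )
        motions.append(MotionTrace(mdf.values, subject_id=sid))
    truth_path = data_dir / "ground_truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    return CohortData(None, series, motions, manifest, truth)


def preprocess_subject(
    ts: RoiTimeSeries,
    motion: MotionTrace,
    n_discard: int = 10,
    band: tuple[float, float] = (0.01, 0.10),
    gsr: bool = False,
    extra_regressors: np.ndarray | None = None,
) -> RoiTimeSeries:
    """discard -> nuisance regression (Friston-24 [+ GSR] [+ extras])
    -> band-pass, sharing the discard with the motion-derived
    regressors."""
    ts = discard_initial(ts, n_discard)
    reg = friston24(motion)[n_discard:]
    if extra_regressors is not None:
        reg = np.column_stack([reg, np.asarray(extra_regressors)[n_discard:]])
    if gsr:
        reg = np.column_stack([reg, ts.data.mean(axis=1)])
    ts = nuisance_regress(ts, reg)
    return bandpass(ts, band[0], band[1])


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write the output tables.

    Writes ``qc_report.tsv``, ``features.tsv``, ``group_stats.tsv``,
    ``correlations.tsv``, ``config.yaml`` and ``run_log.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
    elif config.data_dir:
        cohort = load_cohort_dir(config.data_dir)
    else:
        raise ValueError("config needs either 'simulate' or 'data_dir'")

    R = cohort.series[0].n_rois
    if config.parcellation_path:
        parc = load_parcellation(config.parcellation_path)
    elif R == 116:
        parc = default_parcellation()
    else:
        parc = _generic_parcellation(R)
    if parc.n_rois != R:
        raise ValueError(
            f"parcellation has {parc.n_rois} ROIs but series have {R}"
        )

    # ---- QC ----------------------------------------------------------
    qc = qc_exclude(
        {m.subject_id: m for m in cohort.motion}, threshold=config.fd_threshold
    )
    qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    kept_ids = set(qc.loc[qc["kept"], "subject_id"])
    if config.include_subjects is not None:
        kept_ids &= set(config.include_subjects)
    logger.info("QC kept %d / %d subjects", len(kept_ids), len(qc))

    # ---- preprocess + features --------------------------------------
    extractor = TemporalVariabilityExtractor(
        parc,
        lengths=tuple(config.lengths),
        min_windows=config.min_windows,
        fisher_z=config.fisher_z,
    )
    kept_series = []
    kept_rows = []
    for ts, motion in zip(cohort.series, cohort.motion):
        if ts.subject_id not in kept_ids:
            continue
        clean = preprocess_subject(
            ts, motion, n_discard=config.n_discard, band=tuple(config.band), gsr=config.gsr
        )
        kept_series.append(clean.data)
        kept_rows.append(ts.subject_id)
    if not kept_series:
        raise ValueError("no subjects survived QC")
    extractor.fit(kept_series)
    feats = extractor.transform(kept_series)
    features = pd.DataFrame(
        feats, columns=extractor.get_feature_names_out(), index=pd.Index(kept_rows, name="subject_id")
    )
    n_seg = extractor.n_segmentations_
    features["n_segmentations_used"] = [
        n_seg[s.shape[0]] for s in kept_series
    ]
    features.reset_index().to_csv(
        outdir / "features.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # ---- statistics --------------------------------------------------
    manifest = cohort.manifest.set_index("subject_id").loc[kept_rows].reset_index()
    manifest["mean_fd"] = [
        m.mean_fd for m in cohort.motion if m.subject_id in set(kept_rows)
    ]
    feat_cols = [c for c in features.columns if c != "n_segmentations_used"]
    feats_only = features[feat_cols].reset_index(drop=True)
    stats_table = group_comparison(
        feats_only,
        manifest,
        covariates=tuple(config.covariates),
        gate_alpha=config.gate_alpha,
        alpha=config.alpha,
        fdr=config.fdr,
    )
    stats_table.to_csv(
        outdir / "group_stats.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    sig_feats = sorted(
        stats_table.loc[stats_table["significant"].fillna(False), "feature"].unique()
    )
    scores = [s for s in (*PATIENT_SCORES, *COGNITIVE_SCORES) if s in manifest.columns]
    corr = clinical_correlations(feats_only, manifest, scores, feature_names=sig_feats)
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # ---- provenance --------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    undefined_counts = {
        c: int(features[c].isna().sum()) for c in feat_cols if features[c].isna().any()
    }
    log = {
        "tvfc_version": __version__,
        "config_hash": config.config_hash(),
        "n_subjects_input": int(len(qc)),
        "n_subjects_kept": int(len(kept_rows)),
        "n_segmentations_used": {str(k): v for k, v in n_seg.items()},
        "undefined_feature_counts": undefined_counts,
        "parcellation_checksum": parc.labels_checksum(),
        "n_significant_features": int(len(sig_feats)),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return outdir


def _generic_parcellation(R: int) -> Parcellation:
    """Even split of R ROIs into up to 4 generic networks, for
    simulations that do not use the packaged atlas."""
    labels = tuple(f"roi_{i + 1:03d}" for i in range(R))
    n_nets = min(4, max(2, R // 3))
    nets = tuple(f"net_{(i * n_nets) // R + 1}" for i in range(R))
    return Parcellation(labels, nets)
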