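"""End-to-end orchestration: simulate -> preprocess -> features -> transform
-> rank -> classify -> stats, with a run manifest for exact re-execution.

Every stochastic stage draws from a named substream of the single run
seed, so stage order and stage additions never perturb each other's
streams, and a rerun with the same config reproduces every CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import substream_int
from .classify import ClassifierConfig, build_comparisons, cross_validate
from .fuzzy import PartitionConfig
from .hfd import HFDConfig, feature_table
from .preprocess import UnrecoverableRecordingError, preprocess_recording
from .ranking import chi2_rank, correlation_rank, pca_rank, rank_table, significance_rank
from .recording import SubjectRecord
from .stats import stats_report
from .synth import GROUPS, CohortConfig, generate_cohort, read_cohort, write_cohort

log = logging.getLogger("eegfd")

ALL_STAGES = ("simulate", "preprocess", "features", "rank", "classify", "stats")


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    out_dir: str = "eegfd_run"
    seed: int = 0
    input_mode: str = "synthetic"      # synthetic | csv-dir
    input_manifest: str | None = None  # manifest.csv for csv-dir mode
    skip: tuple[str, ...] = ()
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hfd: HFDConfig = field(default_factory=HFDConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    transform: str | None = "crisp"    # None | crisp | graded
    models: tuple[str, ...] = ("mlp", "svm")
    folds: int = 10
    alpha: float = 0.05
    # preprocessing thresholds
    low_hz: float = 1.0
    high_hz: float = 70.0
    notch_hz: float = 50.0
    reject_window_s: float = 1.0
    reject_amp_tol_uv: float = 200.0


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    An unrecoverable stage error aborts the run with the stage named in
    the raised exception; outputs of completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    skip = set(cfg.skip)

    subjects: list[SubjectRecord] | None = None
    try:
        if cfg.input_mode == "synthetic" and "simulate" not in skip:
            cohort_cfg = cfg.cohort
            cohort_cfg.seed = cfg.seed
            subjects = generate_cohort(cohort_cfg)
            mpath = write_cohort(subjects, out / "raw")
            manifest["stages"]["simulate"] = {
                "n_subjects": len(subjects), "manifest": str(mpath)}
            log.info("simulate: %d subjects", len(subjects))
        elif cfg.input_mode != "synthetic":
            if not cfg.input_manifest or not Path(cfg.input_manifest).exists():
                raise FileNotFoundError("input_manifest required in non-synthetic mode")
            subjects = read_cohort(cfg.input_manifest, rate_hz=cfg.cohort.rate_hz)
            manifest["stages"]["load"] = {"n_subjects": len(subjects)}

        if subjects is not None and "preprocess" not in skip:
            cleaned, dropped = [], 0
            for s in subjects:
                recs = []
                for rec in s.recordings:
                    try:
                        recs.append(preprocess_recording(
                            rec, cfg.low_hz, cfg.high_hz, cfg.notch_hz,
                            reject_window_s=cfg.reject_window_s,
                            reject_amp_tol_uv=cfg.reject_amp_tol_uv))
                    except UnrecoverableRecordingError as exc:
                        dropped += 1
                        log.warning("preprocess: dropped a recording of %s (%s)",
                                    s.subject_id, exc)
                cleaned.append(SubjectRecord(s.subject_id, s.group, recs, s.truth))
            subjects = cleaned
            manifest["stages"]["preprocess"] = {"recordings_dropped": dropped}

        features = None
        if subjects is not None and "features" not in skip:
            features = feature_table(subjects, cfg.hfd)
            fpath = out / "features.csv"
            features.to_csv(fpath, index=False)
            manifest["stages"]["features"] = {
                "n_subjects": len(features), "path": str(fpath)}

        if features is not None and "rank" not in skip:
            X = features.drop(columns=["subject_id", "group"]).to_numpy()
            y = features["group"].to_numpy()
            names = [c for c in features.columns if c.startswith("higu_")]
            paths = []
            for method, fn in [("correlation", correlation_rank),
                               ("chi2", chi2_rank),
                               ("significance", significance_rank),
                               ("pca", lambda X_, y_: pca_rank(X_))]:
                table = rank_table(fn(X, y), names)
                p = out / f"rank_{method}.csv"
                table.to_csv(p, index=False)
                paths.append(str(p))
            manifest["stages"]["rank"] = {"paths": paths}

        if features is not None and "classify" not in skip:
            X = features.drop(columns=["subject_id", "group"]).to_numpy()
            y = features["group"].to_numpy()
            schemes = build_comparisons(GROUPS)
            summary = []
            for scheme in schemes:
                for model in cfg.models:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        panel = cross_validate(
                            X, y, scheme, model=model, k=cfg.folds,
                            seed=substream_int(cfg.seed, "classify"),
                            transform=cfg.transform,
                            partition_config=cfg.partition,
                            config=cfg.classifier)
                    fname = f"scheme_{scheme.name.replace(' ', '_')}_{model}.csv"
                    panel.to_frame(decimals=2).to_csv(out / fname)
                    summary.append({"scheme": scheme.name, "model": model,
                                    "weighted_f": float(panel.weighted["f_measure"]),
                                    "weighted_mcc": float(panel.weighted["mcc"])})
            sdf = pd.DataFrame(summary)
            best = (sdf.sort_values(["scheme", "weighted_f"], ascending=[True, False])
                    .groupby("scheme", sort=False).head(1))
            sdf.to_csv(out / "classification_summary.csv", index=False)
            manifest["stages"]["classify"] = {
                "n_schemes": len(schemes),
                "selection_rule": "best model per scheme by weighted F-measure",
                "best": best.to_dict(orient="records"),
            }

        if features is not None and "stats" not in skip:
            report = stats_report(features, features["group"].to_numpy(),
                                  alpha=cfg.alpha)
            report.to_csv(out / "stats_report.csv", index=False)
            manifest["stages"]["stats"] = {
                "n_significant": int(report["significant"].sum()),
                "path": str(out / "stats_report.csv"),
            }
    except UnrecoverableRecordingError as exc:
        manifest["aborted"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
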