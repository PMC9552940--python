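"""End-to-end orchestration: simulate -> process -> featurize -> train-eval.

Each stage consumes and produces documented plain-text intermediates, so
any stage is independently testable and the pipeline is resumable: a
stage whose outputs already exist is skipped.  Every output directory
carries a provenance block (full configuration, its hash, and the stage
seeds).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import acpw as acpw_mod
from . import io as io_mod
from .beats import PulseTrain, segment_beats
from .features import build_feature_table, read_feature_table, write_feature_table
from .hemo import mask_artifacts, resample
from .mlcore import RFConfig, run_cv
from .synthgen import GeneratorParams, GroundTruth, Recording, make_subject

__all__ = [
    "ProcessingParams",
    "PipelineConfig",
    "process_recording",
    "cohort_feature_table",
    "run_pipeline",
    "PipelineError",
]

MODALITIES = ("dHbO", "dHbT", "CBF")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class ProcessingParams:
    """Signal-processing constants of the ACPW pipeline."""

    window: int = 120
    step: int = 20
    n_points: int = 66
    z_thresh: float = 3.0
    icp_max: float = 30.0
    kalman_q: float = 1e-3
    kalman_r: float = 1e-2
    jump_sd_thresh: float = 10.0
    artifact_pad_s: float = 2.0
    fs_target: float = 50.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    rf: RFConfig = field(default_factory=RFConfig)
    cv_folds: int = 5
    cv_seed: int = 0
    modalities: tuple[str, ...] = MODALITIES

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "processing": self.processing.to_dict(),
            "rf": self.rf.to_dict(),
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "modalities": list(self.modalities),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        gen = GeneratorParams(**{
            **doc.get("generator", {}),
            **(
                {"icp_levels": tuple(doc["generator"]["icp_levels"])}
                if "icp_levels" in doc.get("generator", {}) else {}
            ),
            **(
                {"heart_rate_bpm": tuple(doc["generator"]["heart_rate_bpm"])}
                if "heart_rate_bpm" in doc.get("generator", {}) else {}
            ),
        })
        return cls(
            generator=gen,
            processing=ProcessingParams(**doc.get("processing", {})),
            rf=RFConfig(**doc.get("rf", {})),
            cv_folds=doc.get("cv_folds", 5),
            cv_seed=doc.get("cv_seed", 0),
            modalities=tuple(doc.get("modalities", MODALITIES)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def process_recording(
    rec: Recording,
    params: ProcessingParams | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> list[acpw_mod.ACPW]:
    """Recording -> cleaned ACPWs for every requested modality.

    Per trial: auxiliary channels are resampled to 50 Hz, each optical
    channel is artifact-masked, beats are segmented from the R-peak
    train, 120-beat sliding averages are formed, z-score outliers are
    rejected, the Kalman filter smooths the trial, and waveforms above
    the ICP ceiling are dropped.
    """
    p = params or ProcessingParams()
    out: list[acpw_mod.ACPW] = []
    for trial in rec.trials:
        icp50 = resample(trial.channels["ICP"], p.fs_target)
        abp50 = resample(trial.channels["ABP"], p.fs_target)
        rp50 = resample(trial.rpeaks, p.fs_target)
        peaks = PulseTrain(rp50.samples, rp50.fs)
        for modality in modalities:
            if modality not in trial.channels:
                continue
            ch = trial.channels[modality]
            if ch.fs != p.fs_target:
                ch = resample(ch, p.fs_target)
            ch = mask_artifacts(ch, p.jump_sd_thresh, p.artifact_pad_s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beats = segment_beats(
                    ch, peaks, icp=icp50, map_=abp50,
                    subject_id=rec.subject_id, trial_id=trial.trial_id,
                )
                raw = acpw_mod.sliding_average(beats, p.window, p.step, modality=modality)
                kept, _ = acpw_mod.zscore_reject(raw, p.z_thresh)
                smooth = acpw_mod.kalman_smooth(kept, p.kalman_q, p.kalman_r)
                out.extend(acpw_mod.filter_icp_range(smooth, p.icp_max))
    return out


def cohort_feature_table(config: PipelineConfig) -> pd.DataFrame:
    """Simulate the whole cohort in memory and featurize it."""
    acpws = []
    for i in range(config.generator.n_subjects):
        rec, _ = make_subject(config.generator, i)
        acpws.extend(process_recording(rec, config.processing, config.modalities))
    if not acpws:
        raise PipelineError("featurize", "no ACPWs produced (all filtered?)")
    return build_feature_table(acpws)


def _provenance(config: PipelineConfig) -> dict:
    return {"config": config.to_dict(), "config_hash": config.config_hash()}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages, writing intermediates and the final report.

    Stages are idempotent: existing stage outputs (matched by config
    hash) are reused, so rerunning in the same directory resumes and
    reproduces the identical report.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    prov_file = out / "provenance.json"
    if prov_file.exists():
        old = json.loads(prov_file.read_text())
        if old.get("config_hash") != prov["config_hash"]:
            raise PipelineError("setup", "output directory holds a different config")
    else:
        prov_file.write_text(json.dumps(prov, indent=1))

    timings = {}

    # simulate
    t0 = time.monotonic()
    raw_dir = out / "raw"
    recs: list[tuple[Recording, GroundTruth]] = []
    for i in range(config.generator.n_subjects):
        sid = f"S{i:02d}"
        if not (raw_dir / sid / "recording.json").exists():
            rec, gt = make_subject(config.generator, i)
            io_mod.write_recording(rec, raw_dir)
            io_mod.write_ground_truth(gt, out / "truth")
            recs.append((rec, gt))
        else:
            recs.append((io_mod.read_recording(raw_dir / sid), None))
    timings["simulate_s"] = round(time.monotonic() - t0, 2)

    # process + featurize
    t0 = time.monotonic()
    feat_file = out / "features.csv"
    if feat_file.exists():
        table = read_feature_table(feat_file)
    else:
        acpws = []
        for rec, _ in recs:
            acpws.extend(process_recording(rec, config.processing, config.modalities))
        if not acpws:
            raise PipelineError("featurize", "no ACPWs produced (all filtered?)")
        acpw_mod.write_acpws(acpws, out / "acpws.csv")
        write_feature_table(build_feature_table(acpws), feat_file)
        # re-read so fresh and resumed runs train on byte-identical inputs
        table = read_feature_table(feat_file)
    timings["process_s"] = round(time.monotonic() - t0, 2)

    # train-eval per modality
    t0 = time.monotonic()
    report: dict = {"modalities": {}, **prov}
    for modality in config.modalities:
        if not (table["modality"] == modality).any():
            raise PipelineError("train-eval", f"no feature rows for {modality}")
        rep = run_cv(table, modality, config.rf, k=config.cv_folds, seed=config.cv_seed)
        report["modalities"][modality] = rep.summary()
        pd.DataFrame({"ICPest": rep.predictions, "ICPinv": rep.labels}).to_csv(
            out / f"predictions_{modality}.csv", index=False
        )
    timings["train_eval_s"] = round(time.monotonic() - t0, 2)
    print(f"[pulseicp] stage timings: {timings}", file=sys.stderr)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return out
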