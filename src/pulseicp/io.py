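"""Plain-text serialization of recordings and ground truth.

One directory per subject.  Each channel of each trial is a two-column
CSV (``time_s,value``); the R-peak train is a one-column index CSV.  A
``recording.json`` sidecar carries sampling rates, trial boundaries and
subject metadata, and ``ground_truth.json`` + per-trial ``true_*`` CSVs
carry the planted latent truth (beat boundaries, per-beat ICP and heart
rate — enough to regenerate every noiseless beat template
deterministically — plus artifact intervals and outlier-beat indices).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hemo import Channel
from .synthgen import GroundTruth, Recording, Trial

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "read_trace",
]

_CHANNEL_ORDER = ["dHbO", "dHbT", "CBF", "ABP", "ICP"]


def read_trace(path, label: str, fs: float | None = None, units: str = "") -> Channel:
    """Import an external two-column (``time_s,value``) plain-text trace.

    The sampling rate is taken from the time column's median spacing
    unless given explicitly; the grid must be regular to 1%.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a two-column time_s,value file")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if len(dt) == 0 or np.median(dt) <= 0:
            raise ValueError("cannot infer sampling rate from time column")
        if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt):
            raise ValueError("irregular time grid; pass fs explicitly")
        fs = 1.0 / float(np.median(dt))
    return Channel(v, fs, label, units)


def write_recording(rec: Recording, outdir) -> Path:
    out = Path(outdir) / rec.subject_id
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"subject_id": rec.subject_id, "meta": rec.meta, "trials": []}
    for trial in rec.trials:
        entry = {"trial_id": trial.trial_id, "target_icp": trial.target_icp, "channels": {}}
        for label, ch in trial.channels.items():
            fname = f"{trial.trial_id}_{label}.csv"
            pd.DataFrame({"time_s": ch.time_s, "value": ch.samples}).to_csv(
                out / fname, index=False, float_format="%.10g"
            )
            entry["channels"][label] = {"file": fname, "fs": ch.fs, "units": ch.units}
        rfname = f"{trial.trial_id}_Rpeaks.csv"
        pd.DataFrame({"index": trial.rpeaks.samples}).to_csv(out / rfname, index=False)
        entry["rpeaks"] = {"file": rfname, "fs": trial.rpeaks.fs}
        sidecar["trials"].append(entry)
    (out / "recording.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_recording(subject_dir) -> Recording:
    d = Path(subject_dir)
    sidecar = json.loads((d / "recording.json").read_text())
    trials = []
    for entry in sidecar["trials"]:
        channels = {}
        for label, info in entry["channels"].items():
            df = pd.read_csv(d / info["file"])
            channels[label] = Channel(
                df["value"].to_numpy(), info["fs"], label, info.get("units", "")
            )
        rdf = pd.read_csv(d / entry["rpeaks"]["file"])
        rpeaks = Channel(rdf["index"].to_numpy(), entry["rpeaks"]["fs"], "Rpeaks")
        trials.append(Trial(entry["trial_id"], entry["target_icp"], channels, rpeaks))
    return Recording(sidecar["subject_id"], trials, sidecar.get("meta", {}))


def write_ground_truth(gt: GroundTruth, outdir) -> Path:
    out = Path(outdir) / gt.subject_id
    out.mkdir(parents=True, exist_ok=True)
    doc = {"subject_id": gt.subject_id, "trials": {}}
    for key in gt.beat_bounds:
        trial_id = key.split("/", 1)[1]
        doc["trials"][trial_id] = {
            "beat_bounds": gt.beat_bounds[key].tolist(),
            "beat_icp": gt.beat_icp[key].tolist(),
            "beat_hr": gt.beat_hr[key].tolist(),
            "artifacts": [list(ev) for ev in gt.artifacts[key]],
            "outlier_beats": gt.outlier_beats[key].tolist(),
        }
        for name, arr in (("true_icp", gt.true_icp[key]), ("true_map", gt.true_map[key])):
            pd.DataFrame({"value": arr}).to_csv(
                out / f"{trial_id}_{name}.csv", index=False, float_format="%.10g"
            )
    (out / "ground_truth.json").write_text(json.dumps(doc, indent=1))
    return out


def read_ground_truth(subject_dir) -> GroundTruth:
    d = Path(subject_dir)
    doc = json.loads((d / "ground_truth.json").read_text())
    gt = GroundTruth(subject_id=doc["subject_id"])
    for trial_id, entry in doc["trials"].items():
        key = f"{doc['subject_id']}/{trial_id}"
        gt.beat_bounds[key] = np.asarray(entry["beat_bounds"], dtype=np.int64)
        gt.beat_icp[key] = np.asarray(entry["beat_icp"], dtype=float)
        gt.beat_hr[key] = np.asarray(entry["beat_hr"], dtype=float)
        gt.artifacts[key] = [tuple(ev) for ev in entry["artifacts"]]
        gt.outlier_beats[key] = np.asarray(entry["outlier_beats"], dtype=np.int64)
        gt.true_icp[key] = pd.read_csv(d / f"{trial_id}_true_icp.csv")["value"].to_numpy()
        gt.true_map[key] = pd.read_csv(d / f"{trial_id}_true_map.csv")["value"].to_numpy()
    return gt
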