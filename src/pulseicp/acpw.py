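"""Averaged cardiac pulse waveforms (ACPWs).

Single beats are ensemble averaged over sliding 120-beat windows (20-beat
step, 83.3% overlap), each beat having first been spline-resampled to 66
points and min-max scaled.  Per-trial outlier waveforms are rejected by a
pointwise z-score rule, a one-dimensional-per-point Kalman filter tracks
the trial's ideal pulse and pulls each waveform toward it, and waveforms
whose window-mean ICP exceeds 30 mmHg are discarded as too scarce to
learn from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .beats import Beat

__all__ = [
    "ACPW",
    "N_POINTS",
    "normalize",
    "sliding_average",
    "zscore_reject",
    "kalman_smooth",
    "filter_icp_range",
    "write_acpws",
    "read_acpws",
]

#: samples per normalized waveform (1.32 s at 50 Hz)
N_POINTS = 66


@dataclass
class ACPW:
    """One averaged cardiac pulse waveform with its window labels."""

    y: np.ndarray
    mean_icp: float
    mean_map: float
    modality: str
    subject_id: str = ""
    trial_id: str = ""
    window_index: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.y) != N_POINTS:
            raise ValueError(f"ACPW must have {N_POINTS} samples, got {len(self.y)}")


def normalize(y: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Spline-resample a beat to ``n_points`` and min-max scale to [0, 1].

    Cubic-spline interpolation onto evenly spaced abscissae over the
    beat's duration, then ``(y - min) / (max - min)``.  A constant input
    has no amplitude to normalize and comes back as all zeros (the
    degenerate case; a warning is issued).
    """
    y = np.asarray(y, dtype=np.float64)
    if len(y) < 4:
        raise ValueError("need at least 4 samples to spline-normalize a beat")
    x = np.linspace(0.0, 1.0, len(y))
    out = CubicSpline(x, y)(np.linspace(0.0, 1.0, n_points))
    rng = out.max() - out.min()
    if rng <= 0:
        warnings.warn("constant beat: degenerate normalization to zeros")
        return np.zeros(n_points)
    return (out - out.min()) / rng


def sliding_average(
    beats: list[Beat], window: int = 120, step: int = 20, modality: str = "",
) -> list[ACPW]:
    """Ensemble average normalized beats over sliding windows.

    Each beat is normalized (66 points, unit amplitude), the window's
    pointwise mean is re-min-max scaled, and the window's ICP/MAP labels
    are the means of the member beats' raw means.  Window count is
    ``floor((n - window)/step) + 1`` for ``n >= window``, else zero.
    """
    if not window > step > 0:
        raise ValueError("need window > step > 0")
    n = len(beats)
    if n < window:
        warnings.warn(f"only {n} beats for a {window}-beat window: no ACPWs")
        return []
    norm = np.stack([normalize(b.samples) for b in beats])
    icps = np.array([b.mean_icp_raw for b in beats])
    maps = np.array([b.mean_map_raw for b in beats])
    subject = beats[0].subject_id
    trial = beats[0].trial_id
    out = []
    n_windows = (n - window) // step + 1
    for w in range(n_windows):
        sl = slice(w * step, w * step + window)
        y = norm[sl].mean(axis=0)
        rng = y.max() - y.min()
        degenerate = rng <= 0
        y = np.zeros(N_POINTS) if degenerate else (y - y.min()) / rng
        out.append(
            ACPW(
                y,
                mean_icp=float(np.mean(icps[sl])),
                mean_map=float(np.mean(maps[sl])),
                modality=modality,
                subject_id=subject,
                trial_id=trial,
                window_index=w,
                degenerate=degenerate,
            )
        )
    return out


def zscore_reject(
    acpws: list[ACPW], thresh: float = 3.0
) -> tuple[list[ACPW], list[ACPW]]:
    """Reject whole-waveform outliers within a trial.

    The trial's pointwise mean and SD waveforms are computed across all
    ACPWs; each waveform's score is the mean over the 66 points of
    ``|y_i - mean_i| / sd_i``, and waveforms scoring above ``thresh`` are
    rejected.  With fewer than three waveforms the statistics are
    meaningless and everything is kept.
    """
    if len(acpws) < 3:
        if acpws:
            warnings.warn("fewer than 3 ACPWs: z-score rejection skipped")
        return list(acpws), []
    ys = np.stack([a.y for a in acpws])
    mu = ys.mean(axis=0)
    sd = ys.std(axis=0)
    safe = np.where(sd > 1e-12, sd, 1.0)
    scores = np.mean(np.abs(ys - mu) / safe, axis=1)
    kept = [a for a, s in zip(acpws, scores) if s <= thresh]
    rejected = [a for a, s in zip(acpws, scores) if s > thresh]
    return kept, rejected


def kalman_smooth(
    acpws: list[ACPW], q: float = 1e-3, r: float = 1e-2
) -> list[ACPW]:
    """Pull each waveform toward the trial's Kalman-tracked ideal pulse.

    A 66-dimensional ideal-pulse state evolves as an independent
    per-point random walk (process noise ``q``); each observed waveform
    updates it with the scalar gain ``K = P/(P + r)``.  The emitted
    waveform blends observation and state,
    ``y' = y - (1 - w)(y - x_hat)``, where the blend weight
    ``w = P/(P + r)`` (clipped to [0, 1]) trusts the observation in
    proportion to the state uncertainty, then is re-min-max normalized.
    Large ``q`` makes the filter trust observations fully
    (output = input); small ``q`` pulls hard toward the running ideal
    pulse.
    """
    if not acpws:
        return []
    if q < 0 or r <= 0:
        raise ValueError("need q >= 0 and r > 0")
    order = sorted(range(len(acpws)), key=lambda i: acpws[i].window_index)
    xhat = acpws[order[0]].y.copy()
    p = r
    out: list[ACPW] = [None] * len(acpws)  # type: ignore[list-item]
    first = True
    for i in order:
        a = acpws[i]
        if first:
            first = False
        else:
            p = p + q
            k = p / (p + r)
            xhat = xhat + k * (a.y - xhat)
            p = (1.0 - k) * p
        w = float(np.clip(p / (p + r), 0.0, 1.0))
        y = a.y - (1.0 - w) * (a.y - xhat)
        rng = y.max() - y.min()
        y = np.zeros(N_POINTS) if rng <= 0 else (y - y.min()) / rng
        out[i] = ACPW(
            y,
            mean_icp=a.mean_icp,
            mean_map=a.mean_map,
            modality=a.modality,
            subject_id=a.subject_id,
            trial_id=a.trial_id,
            window_index=a.window_index,
            degenerate=a.degenerate or rng <= 0,
        )
    return out


def filter_icp_range(acpws: list[ACPW], max_icp: float = 30.0) -> list[ACPW]:
    """Drop waveforms whose window-mean ICP exceeds ``max_icp`` mmHg."""
    kept = [a for a in acpws if a.mean_icp <= max_icp]
    removed = len(acpws) - len(kept)
    if removed:
        warnings.warn(f"filter_icp_range: removed {removed} ACPWs above {max_icp} mmHg")
    return kept


_META_COLS = ["modality", "subject_id", "trial_id", "window_index", "mean_icp", "mean_map"]


def write_acpws(acpws: list[ACPW], path) -> None:
    """Serialize ACPWs to CSV: metadata columns then y_00..y_65."""
    rows = []
    for a in acpws:
        row = {
            "modality": a.modality,
            "subject_id": a.subject_id,
            "trial_id": a.trial_id,
            "window_index": a.window_index,
            "mean_icp": a.mean_icp,
            "mean_map": a.mean_map,
        }
        row.update({f"y_{i:02d}": v for i, v in enumerate(a.y)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_acpws(path) -> list[ACPW]:
    df = pd.read_csv(path)
    ycols = [f"y_{i:02d}" for i in range(N_POINTS)]
    missing = set(_META_COLS + ycols) - set(df.columns)
    if missing:
        raise ValueError(f"ACPW file missing columns: {sorted(missing)}")
    return [
        ACPW(
            row[ycols].to_numpy(dtype=float),
            mean_icp=float(row["mean_icp"]),
            mean_map=float(row["mean_map"]),
            modality=str(row["modality"]),
            subject_id=str(row["subject_id"]),
            trial_id=str(row["trial_id"]),
            window_index=int(row["window_index"]),
        )
        for _, row in df.iterrows()
    ]
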