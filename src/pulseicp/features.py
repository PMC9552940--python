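"""Engineered waveform features for ICP regression.

Eight human-interpretable features per averaged cardiac pulse waveform:
the most prominent interior peak's height (P1pk), position (P1pos),
topographic prominence (P1p) and half-prominence width (P1w); the
centroid coordinates (COMx, COMy) of the polygon bounded by the waveform
and the y = 0 baseline; the trapezoidal area under the curve (AUC); and
the window-mean arterial pressure (MAP).  Time-like features are on the
normalized [0, 1] beat axis, which removes heart rate as a feature.
An undetected peak sets all four peak features to 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .acpw import ACPW, N_POINTS

__all__ = [
    "FEATURE_NAMES",
    "TABLE_COLUMNS",
    "peak_features",
    "centroid",
    "auc",
    "feature_row",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_NAMES = ["P1pk", "P1pos", "P1p", "P1w", "COMx", "COMy", "AUC", "MAP"]
TABLE_COLUMNS = [
    "subject_id",
    "trial_id",
    "window_index",
    "modality",
    *FEATURE_NAMES,
    "label_icp",
]


def peak_features(y: np.ndarray) -> tuple[float, float, float, float]:
    """(P1pk, P1pos, P1p, P1w) of the most prominent interior peak.

    Peaks are detected over the interior samples; the one with greatest
    topographic prominence (earliest on ties) is P1.  Width is measured
    at half prominence.  Position and width are fractions of the [0, 1]
    beat axis.  No interior peak -> all zeros (undetected-feature
    sentinel).
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    peaks, props = sps.find_peaks(y, prominence=0.0)
    if len(peaks) == 0:
        return 0.0, 0.0, 0.0, 0.0
    prom = props["prominences"]
    i = int(np.argmax(prom))  # argmax returns the earliest on ties
    widths, _, _, _ = sps.peak_widths(y, peaks[i : i + 1], rel_height=0.5)
    span = n - 1
    return (
        float(y[peaks[i]]),
        float(peaks[i] / span),
        float(prom[i]),
        float(widths[0] / span),
    )


def centroid(y: np.ndarray) -> tuple[float, float]:
    """Centroid of the polygon under the waveform, by the shoelace formulas.

    The polygon is closed with the y = 0 baseline between the first and
    last abscissae; abscissae are the normalized [0, 1] beat axis.  A
    zero-area polygon returns the (0, 0) sentinel with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    x = np.linspace(0.0, 1.0, n)
    # closed vertex loop: along the curve, then back along the baseline
    px = np.concatenate([x, [x[-1], x[0]]])
    py = np.concatenate([y, [0.0, 0.0]])
    cross = px * np.roll(py, -1) - np.roll(px, -1) * py
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        warnings.warn("zero-area waveform polygon: centroid sentinel (0, 0)")
        return 0.0, 0.0
    cx = ((px + np.roll(px, -1)) * cross).sum() / (6.0 * area)
    cy = ((py + np.roll(py, -1)) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def auc(y: np.ndarray) -> float:
    """Trapezoidal area under the waveform over the [0, 1] beat axis."""
    y = np.asarray(y, dtype=np.float64)
    return float(np.trapezoid(y, dx=1.0 / (len(y) - 1)))


def feature_row(a: ACPW) -> dict:
    """All eight features plus the ICP label for one waveform."""
    p1pk, p1pos, p1p, p1w = peak_features(a.y)
    comx, comy = centroid(a.y) if np.any(a.y != 0) else (0.0, 0.0)
    return {
        "subject_id": a.subject_id,
        "trial_id": a.trial_id,
        "window_index": a.window_index,
        "modality": a.modality,
        "P1pk": p1pk,
        "P1pos": p1pos,
        "P1p": p1p,
        "P1w": p1w,
        "COMx": comx,
        "COMy": comy,
        "AUC": auc(a.y),
        "MAP": a.mean_map,
        "label_icp": a.mean_icp,
    }


def build_feature_table(acpws: list[ACPW]) -> pd.DataFrame:
    """One row per ACPW, deterministically ordered by provenance."""
    if not acpws:
        raise ValueError("no ACPWs to featurize")
    df = pd.DataFrame([feature_row(a) for a in acpws], columns=TABLE_COLUMNS)
    df = df.sort_values(
        ["subject_id", "trial_id", "window_index", "modality"], kind="stable"
    ).reset_index(drop=True)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df[TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df[FEATURE_NAMES + ["label_icp"]].to_numpy())):
        raise ValueError("feature table contains non-finite values")
    return df[TABLE_COLUMNS]
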