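"""R-peak detection and diastole-to-diastole beat segmentation.

R peaks either arrive as a hardware event train or are detected from a
raw EKG channel by reconstructing the QRS band (~10-45 Hz) with a
stationary (maximal-overlap) discrete wavelet transform, squaring the
reconstruction, and peak-picking with a physiological refractory
distance.  Hemodynamic channels are then cut into single beats between
consecutive diastoles, where the diastole for each R peak is the signal
minimum in a short window around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .hemo import Channel

__all__ = ["PulseTrain", "Beat", "detect_r_peaks", "segment_beats"]

QRS_BAND_HZ = (10.0, 45.0)
#: diastole search window around each R peak, seconds
DIASTOLE_WINDOW_S = (-0.25, 0.05)
#: plausible inter-beat interval, seconds
IBI_RANGE_S = (0.25, 1.5)


@dataclass
class PulseTrain:
    """Strictly increasing R-peak sample indices at a stated rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("R-peak indices must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


@dataclass
class Beat:
    """One diastole-to-diastole beat cut from a hemodynamic channel."""

    samples: np.ndarray
    start_index: int
    subject_id: str = ""
    trial_id: str = ""
    mean_icp_raw: float = np.nan
    mean_map_raw: float = np.nan

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def end_index(self) -> int:
        return self.start_index + len(self.samples) - 1


def _qrs_levels(fs: float, max_level: int) -> list[int]:
    """SWT detail levels whose dyadic band overlaps the QRS band."""
    lo, hi = QRS_BAND_HZ
    levels = []
    for j in range(1, max_level + 1):
        band_hi = fs / 2**j
        band_lo = fs / 2 ** (j + 1)
        if band_lo < hi and band_hi > lo:
            levels.append(j)
    return levels or [1]


def detect_r_peaks(ekg: Channel, wavelet: str = "sym4") -> PulseTrain:
    """Detect R peaks by SWT enhancement of the QRS band.

    The EKG is decomposed with an undecimated wavelet transform; detail
    levels covering roughly 10-45 Hz are summed and squared to form an
    envelope, and peaks are picked with a 0.25-s minimum distance and an
    adaptive threshold.  Each envelope peak is refined to the local
    maximum of |EKG| within +/-40 ms.
    """
    x = ekg.samples - np.mean(ekg.samples)
    n = len(x)
    if n == 0 or np.ptp(x) == 0:
        warnings.warn("flat or empty EKG: no R peaks detected")
        return PulseTrain(np.empty(0, dtype=np.int64), ekg.fs)
    max_level = min(8, pywt.swt_max_level(1 << int(np.ceil(np.log2(max(n, 2))))))
    levels = _qrs_levels(ekg.fs, max_level)
    top = max(levels)
    pad_to = int(np.ceil(n / 2**top)) * 2**top
    xp = np.pad(x, (0, pad_to - n), mode="edge")
    # pywt.mra returns [approx, detail_top, ..., detail_1]
    comps = pywt.mra(xp, wavelet, level=top, transform="swt")
    details = comps[1:][::-1]  # details[j-1] is level j
    env = sum(details[j - 1] for j in levels)[:n] ** 2
    dist = max(1, int(round(IBI_RANGE_S[0] * ekg.fs)))
    cand, _ = sps.find_peaks(env, distance=dist)
    if len(cand) == 0:
        warnings.warn("no QRS-band peaks found")
        return PulseTrain(np.empty(0, dtype=np.int64), ekg.fs)
    heights = env[cand]
    thresh = 0.15 * np.median(heights[heights >= np.median(heights)])
    cand = cand[heights > thresh]
    # refine to the local extremum of the raw EKG
    half = max(1, int(round(0.04 * ekg.fs)))
    refined = []
    for c in cand:
        a, b = max(0, c - half), min(n, c + half + 1)
        refined.append(a + int(np.argmax(np.abs(x[a:b]))))
    idx = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce refractory distance after refinement
    if len(idx) > 1:
        keep = [0]
        for i in range(1, len(idx)):
            if idx[i] - idx[keep[-1]] >= dist:
                keep.append(i)
        idx = idx[keep]
    return PulseTrain(idx, ekg.fs)


def segment_beats(
    sig: Channel,
    peaks: PulseTrain,
    icp: Channel | None = None,
    map_: Channel | None = None,
    subject_id: str = "",
    trial_id: str = "",
) -> list[Beat]:
    """Cut a hemodynamic channel into diastole-to-diastole beats.

    For each R peak, the diastole is the signal minimum in the window
    [R-0.25 s, R+0.05 s] (earliest sample on ties).  Beat k spans the
    samples between diastoles k and k+1, inclusive of both boundaries,
    so consecutive beats tile the record sharing boundary samples.
    Beats overlapping any masked artifact sample, or with an implausible
    inter-beat interval, are dropped.  Window-mean raw ICP and MAP over
    the beat span are attached when those channels are given (they must
    share the 50-Hz timebase).
    """
    if peaks.fs != sig.fs:
        raise ValueError("signal and pulse train must share a timebase")
    if len(peaks) < 2:
        return []
    y = sig.samples
    n = len(y)
    w0 = int(round(DIASTOLE_WINDOW_S[0] * sig.fs))
    w1 = int(round(DIASTOLE_WINDOW_S[1] * sig.fs))
    diastoles = []
    for r in peaks.indices:
        a, b = max(0, r + w0), min(n, r + w1 + 1)
        if b <= a:
            continue
        diastoles.append(a + int(np.argmin(y[a:b])))
    d = np.unique(np.asarray(diastoles, dtype=np.int64))
    beats: list[Beat] = []
    lo = int(np.ceil(IBI_RANGE_S[0] * sig.fs))
    hi = int(np.floor(IBI_RANGE_S[1] * sig.fs))
    n_dropped = 0
    for k in range(len(d) - 1):
        a, b = int(d[k]), int(d[k + 1])
        ibi = b - a
        if not lo <= ibi <= hi or ibi + 1 < 8:
            n_dropped += 1
            continue
        if sig.artifact_mask[a : b + 1].any():
            n_dropped += 1
            continue
        beat = Beat(
            y[a : b + 1],
            start_index=a,
            subject_id=subject_id,
            trial_id=trial_id,
            mean_icp_raw=float(np.mean(icp.samples[a : b + 1])) if icp is not None else np.nan,
            mean_map_raw=float(np.mean(map_.samples[a : b + 1])) if map_ is not None else np.nan,
        )
        beats.append(beat)
    if n_dropped:
        warnings.warn(f"segment_beats: dropped {n_dropped} beats (mask/interval)")
    return beats
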