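"""Hemoglobin conversion, channel resampling, and artifact masking.

Optical-density changes at two wavelengths (690 and 830 nm) are converted
to changes in oxy-, deoxy-, and total hemoglobin concentration with the
modified Beer-Lambert law (MBLL).  Auxiliary channels recorded at other
rates (arterial pressure, intracranial pressure, cerebral blood flow,
R-peak event trains) are brought onto the common 50-Hz timebase, and
instability artifacts are masked with a robust jump detector so that
downstream beat windows can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_dilation

__all__ = [
    "Channel",
    "ExtinctionModel",
    "DEFAULT_EXTINCTION_UM_CM",
    "mbll_invert",
    "resample",
    "mask_artifacts",
]

#: Molar extinction coefficients for HbO2 and Hb at 690 and 830 nm,
#: in 1/(uM cm), from the Gratzer/Prahl compilation of hemoglobin
#: spectra (values tabulated in 1/(M cm) divided by 1e6).  Overridable
#: through :class:`ExtinctionModel`.
DEFAULT_EXTINCTION_UM_CM: dict[int, dict[str, float]] = {
    690: {"HbO2": 276.0e-6, "Hb": 2051.96e-6},
    830: {"HbO2": 974.0e-6, "Hb": 693.04e-6},
}

EVENT_LABELS = {"Rpeaks"}


@dataclass
class Channel:
    """One recorded channel: samples at a fixed rate plus an artifact mask.

    ``samples`` are floating point for continuous channels; for the event
    channel label ``Rpeaks`` they are integer sample indices referenced to
    ``fs``.  ``artifact_mask`` is a boolean array of the same length as
    ``samples`` marking samples to exclude downstream.
    """

    samples: np.ndarray
    fs: float
    label: str
    units: str = ""
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        dtype = np.int64 if self.label in EVENT_LABELS else np.float64
        self.samples = np.asarray(self.samples, dtype=dtype)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.samples), dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != len(self.samples):
            raise ValueError("artifact_mask length must match samples length")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class ExtinctionModel:
    """MBLL coefficients: extinction matrix, pathlength factors, distance.

    ``epsilon`` is the 2x2 matrix of molar extinction coefficients with
    rows = wavelengths (690, 830 nm) and columns = chromophores
    (HbO2, Hb), in 1/(uM cm).  Only the DPF *ratio* matters to waveform
    shape after amplitude normalization; the absolute DPF at 830 nm sets
    the concentration scale.
    """

    epsilon: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [DEFAULT_EXTINCTION_UM_CM[690]["HbO2"], DEFAULT_EXTINCTION_UM_CM[690]["Hb"]],
                [DEFAULT_EXTINCTION_UM_CM[830]["HbO2"], DEFAULT_EXTINCTION_UM_CM[830]["Hb"]],
            ]
        )
    )
    dpf830: float = 4.0
    dpf_ratio: float = 1.1  # DPF690 / DPF830
    distance_cm: float = 1.5

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (2, 2):
            raise ValueError("epsilon must be 2x2 (wavelengths x chromophores)")
        if abs(np.linalg.det(self.epsilon)) < 1e-300:
            raise ValueError("extinction matrix is singular")
        if self.dpf_ratio <= 0 or self.dpf830 <= 0 or self.distance_cm <= 0:
            raise ValueError("dpf830, dpf_ratio and distance_cm must be positive")

    @property
    def dpf(self) -> np.ndarray:
        """(DPF690, DPF830)."""
        return np.array([self.dpf_ratio * self.dpf830, self.dpf830])

    def system_matrix(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ (dHbO, dHb)."""
        a = self.epsilon * self.distance_cm * self.dpf[:, None]
        if abs(np.linalg.det(a)) < 1e-300:
            raise ValueError("MBLL system matrix is singular")
        return a


def mbll_invert(
    dod690: Channel, dod830: Channel, model: ExtinctionModel
) -> tuple[Channel, Channel, Channel]:
    """Invert the MBLL: optical-density changes -> hemoglobin changes (uM).

    Solves, per sample, ``dOD_l = sum_c eps_{c,l} dC_c d DPF_l`` for the
    two chromophores and returns (dHbO, dHb, dHbT) with
    ``dHbT = dHbO + dHb`` exactly.
    """
    if len(dod690.samples) != len(dod830.samples):
        raise ValueError("dOD channels must have equal length")
    if dod690.fs != dod830.fs:
        raise ValueError("dOD channels must share a sampling rate")
    a = model.system_matrix()
    conc = np.linalg.solve(a, np.vstack([dod690.samples, dod830.samples]))
    mask = dod690.artifact_mask | dod830.artifact_mask
    fs = dod690.fs
    dhbo = Channel(conc[0], fs, "dHbO", "uM", mask.copy())
    dhb = Channel(conc[1], fs, "dHb", "uM", mask.copy())
    dhbt = Channel(conc[0] + conc[1], fs, "dHbT", "uM", mask.copy())
    return dhbo, dhb, dhbt


def resample(ch: Channel, fs_target: float = 50.0) -> Channel:
    """Bring a channel onto the target (50-Hz) grid.

    Continuous channels are anti-alias filtered and decimated with a
    polyphase filter; event channels (R-peak index trains) are remapped to
    the nearest target-grid sample.  Artifact masks are carried over by
    marking every target sample that any masked source sample maps to,
    then dilating by one sample.
    """
    if ch.label in EVENT_LABELS:
        idx = np.round(ch.samples * fs_target / ch.fs).astype(np.int64)
        idx = np.unique(idx)
        return Channel(idx, fs_target, ch.label, ch.units)
    if fs_target == ch.fs:
        return Channel(ch.samples.copy(), ch.fs, ch.label, ch.units, ch.artifact_mask.copy())
    if fs_target > ch.fs:
        raise ValueError("upsampling a continuous channel is not supported")
    frac = Fraction(fs_target / ch.fs).limit_denominator(1000)
    y = sps.resample_poly(ch.samples, frac.numerator, frac.denominator, padtype="line")
    mask = np.zeros(len(y), dtype=bool)
    if ch.artifact_mask.any():
        src = np.flatnonzero(ch.artifact_mask)
        tgt = np.round(src * fs_target / ch.fs).astype(np.int64)
        tgt = tgt[(tgt >= 0) & (tgt < len(y))]
        mask[tgt] = True
        mask = binary_dilation(mask, iterations=1)
    return Channel(y, fs_target, ch.label, ch.units, mask)


def mask_artifacts(
    ch: Channel, jump_sd_thresh: float = 10.0, pad_s: float = 2.0
) -> Channel:
    """Mask instability artifacts by robust first-difference jump detection.

    Samples whose first difference deviates from the median difference by
    more than ``jump_sd_thresh`` robust standard deviations (MAD-scaled)
    are masked, padded by ``pad_s`` seconds on both sides.  This is an
    automated surrogate for manual removal of laser instabilities; step
    artifacts are caught at their onset and offset edges, so the padding
    should exceed half the longest plausible step duration.
    """
    y = ch.samples
    if len(y) < 3:
        return Channel(y.copy(), ch.fs, ch.label, ch.units, ch.artifact_mask.copy())
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med)) * 1.4826
    mask = np.zeros(len(y), dtype=bool)
    if mad > 0:
        z = np.abs(d - med) / mad
        hits = np.flatnonzero(z > jump_sd_thresh)
        mask[hits] = True
        mask[hits + 1] = True
        pad = int(round(pad_s * ch.fs))
        if pad > 0 and mask.any():
            mask = binary_dilation(mask, structure=np.ones(2 * pad + 1, dtype=bool))
    if mask.all():
        warnings.warn(f"channel {ch.label}: every sample masked as artifact")
    return Channel(y.copy(), ch.fs, ch.label, ch.units, mask | ch.artifact_mask)
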