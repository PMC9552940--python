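"""Synthetic multi-subject hemodynamic recordings with known ground truth.

Emulates stepped intracranial-pressure (ICP) experiments in anesthetized
subjects: each subject contributes several trials, each held near one ICP
target between 5 and 30 mmHg (plus a baseline trial).  Optical channels
(dHbO, dHbT at 50 Hz; a relative cerebral-blood-flow index at 100 Hz) are
built beat by beat from a three-lobe cardiac pulse template whose
morphology broadens and skews rightward as ICP rises.  Arterial pressure
is loosely (linearly + slow noise) coupled to ICP.  Additive noise,
occasional step/spike instability artifacts, and rare 3x-amplitude
outlier beats are planted at configurable rates and logged sample-for-
sample in a :class:`GroundTruth` object, so every downstream stage can be
tested against latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .hemo import Channel, ExtinctionModel

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "Trial",
    "Recording",
    "pulse_template",
    "make_subject",
    "make_cohort",
    "forward_mbll",
    "make_ekg",
]

# Fractional positions/widths/amplitudes of the three pulse lobes
# (percussion, tidal, dicrotic) at zero ICP, on the [0, 1] beat axis.
_LOBE_CENTERS = np.array([0.18, 0.42, 0.68])
_LOBE_WIDTHS = np.array([0.075, 0.12, 0.10])
_LOBE_AMPS = np.array([1.0, 0.55, 0.35])


@dataclass
class GeneratorParams:
    """Study-condition knobs for the synthetic cohort.

    Morphology coefficients are per-mmHg linear sensitivities of the pulse
    template to ICP; their defaults are a declared calibration chosen so
    that waveform shape encodes ICP clearly but imperfectly at the default
    noise level.  ``trial_duration_s`` defaults to a desk-scale 600 s; the
    full-scale experiment (~90-min trials) is the same generator with
    ``trial_duration_s=5400``.
    """

    n_subjects: int = 8
    trials_per_subject: int = 8
    trial_duration_s: float = 600.0
    icp_levels: tuple[float, ...] = (5.0, 8.0, 12.0, 16.0, 20.0, 25.0, 30.0)
    icp_baseline: float = 5.0
    heart_rate_bpm: tuple[float, float] = (93.0, 184.0)
    fs_nirs: float = 50.0
    fs_aux: float = 100.0
    # morphology sensitivities (per mmHg)
    skew_per_mmHg: float = 0.003
    width_per_mmHg: float = 0.02
    notch_decay_per_mmHg: float = 0.01
    # MAP-ICP coupling
    map_base: float = 70.0
    map_slope: float = 0.7
    map_noise_sd: float = 3.0
    # slow within-trial ICP drift amplitude (mmHg) and pulsatile amplitudes
    icp_drift_mmHg: float = 1.0
    icp_pulse_mmHg: float = 1.5
    abp_pulse_mmHg: float = 15.0
    # channel amplitudes (pulse peak-to-baseline) and per-sample noise
    amp_dhbo_uM: float = 0.8
    amp_dhbt_uM: float = 1.0
    amp_cbf: float = 1.0
    noise_sd: float = 0.2
    # beat-to-beat heart-rate jitter (fractional, AR(1))
    hr_jitter_sd: float = 0.02
    # planted corruption rates
    artifact_rate_per_h: float = 2.0
    outlier_beat_rate: float = 0.002
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_nirs <= 0 or self.fs_aux <= 0:
            raise ValueError("sampling rates must be positive")
        if self.trial_duration_s <= 0 or self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("durations and counts must be positive")
        if not all(0 <= v <= 60 for v in self.icp_levels) or not 0 <= self.icp_baseline <= 60:
            raise ValueError("icp_levels must lie in [0, 60] mmHg")
        if self.noise_sd < 0 or self.map_noise_sd < 0 or self.artifact_rate_per_h < 0:
            raise ValueError("noise and artifact rates must be non-negative")
        lo, hi = self.heart_rate_bpm
        if not (0 < lo <= hi):
            raise ValueError("heart_rate_bpm must be an increasing positive pair")

    def trial_targets(self) -> list[float]:
        """Per-trial ICP targets: baseline first, then the stepped levels."""
        targets = [self.icp_baseline]
        i = 0
        while len(targets) < self.trials_per_subject:
            targets.append(self.icp_levels[i % len(self.icp_levels)])
            i += 1
        return targets[: self.trials_per_subject]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trial:
    """One constant-ICP-level trial: channels plus the R-peak event train."""

    trial_id: str
    target_icp: float
    channels: dict[str, Channel]
    rpeaks: Channel  # label "Rpeaks", indices on the 50-Hz grid


@dataclass
class Recording:
    """A subject's trials plus metadata."""

    subject_id: str
    trials: list[Trial]
    meta: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Latent truth aligned with the emitted channels, one entry per trial.

    ``beat_bounds`` are 50-Hz boundary indices (diastoles); beat k spans
    ``bounds[k]..bounds[k+1]`` inclusive (shared boundary sample).
    ``templates`` are the noiseless unit-amplitude 50-Hz beat templates.
    Artifact intervals are (channel_label, start_s, end_s) triples.
    """

    subject_id: str
    beat_bounds: dict[str, np.ndarray] = field(default_factory=dict)
    templates: dict[str, list[np.ndarray]] = field(default_factory=dict)
    beat_icp: dict[str, np.ndarray] = field(default_factory=dict)
    beat_hr: dict[str, np.ndarray] = field(default_factory=dict)
    true_icp: dict[str, np.ndarray] = field(default_factory=dict)  # fs_aux
    true_map: dict[str, np.ndarray] = field(default_factory=dict)  # fs_aux
    artifacts: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    outlier_beats: dict[str, np.ndarray] = field(default_factory=dict)


def _template_on_grid(t: np.ndarray, icp: float, params: GeneratorParams) -> np.ndarray:
    """Evaluate the three-lobe template on a [0, 1] beat-phase grid.

    Lobe widths grow linearly with ICP, lobe centers shift rightward, and
    the dicrotic lobe amplitude decays exponentially, reproducing the
    broadening/right-skew of the cardiac pulse under raised ICP.  The
    returned beat starts and ends exactly at its minimum (0) and has unit
    amplitude.
    """
    centers = _LOBE_CENTERS + params.skew_per_mmHg * icp
    widths = _LOBE_WIDTHS * (1.0 + params.width_per_mmHg * icp)
    amps = _LOBE_AMPS.copy()
    amps[2] *= np.exp(-params.notch_decay_per_mmHg * icp)
    w = np.zeros_like(t)
    for a, c, s in zip(amps, centers, widths):
        w += a * np.exp(-0.5 * ((t - c) / s) ** 2)
    # remove the linear baseline through the endpoints so the beat starts
    # and ends at zero (diastole-to-diastole convention)
    w = w - (w[0] + (w[-1] - w[0]) * t)
    w = np.clip(w, 0.0, None)
    m = w.max()
    return w / m if m > 0 else w


def pulse_template(icp: float, hr: float, params: GeneratorParams) -> np.ndarray:
    """One unit-amplitude cardiac beat at the given ICP and heart rate.

    Sampled at ``params.fs_nirs`` over one beat period 60/hr s, inclusive
    of both diastole endpoints (length round(fs*60/hr)+1 samples).
    """
    if not 0 <= icp <= 60:
        raise ValueError(f"icp must be in [0, 60] mmHg, got {icp}")
    if not 40 <= hr <= 250:
        raise ValueError(f"heart rate must be in [40, 250] bpm, got {hr}")
    n_int = int(round(params.fs_nirs * 60.0 / hr))
    t = np.linspace(0.0, 1.0, n_int + 1)
    return _template_on_grid(t, icp, params)


def _slow_drift(t: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean drift: two sinusoids with random period and phase."""
    if amp == 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    for frac in (1.0, 0.5):
        period = rng.uniform(120.0, 300.0)
        phase = rng.uniform(0, 2 * np.pi)
        out += frac * np.sin(2 * np.pi * t / period + phase)
    return amp * out / 1.5


def _slow_noise(t: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow colored noise with (asymptotic) RMS ``sd``: random-phase sinusoid sum.

    Periods of 40-400 s, so the noise survives 120-beat window averaging;
    this keeps the emitted MAP only loosely informative about ICP.
    """
    if sd == 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    n_comp = 6
    for _ in range(n_comp):
        period = rng.uniform(40.0, 400.0)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * t / period + phase)
    return sd * out / np.sqrt(n_comp / 2.0)


def _make_trial(
    params: GeneratorParams,
    subject_id: str,
    trial_idx: int,
    target_icp: float,
    hr_subject: float,
    rng: np.random.Generator,
    gt: GroundTruth,
) -> Trial:
    fs, fsa = params.fs_nirs, params.fs_aux
    trial_id = f"t{trial_idx:02d}"

    # --- continuous-time beat grid ------------------------------------
    # beat onset times accumulate 60/hr_k with AR(1) fractional jitter;
    # boundary indices are the nearest 50-Hz samples, so quantization
    # error never accumulates.
    times = [0.0]
    hrs = []
    jitter = 0.0
    while times[-1] < params.trial_duration_s:
        jitter = 0.7 * jitter + np.sqrt(1 - 0.7**2) * rng.normal() * params.hr_jitter_sd
        hr_k = float(np.clip(hr_subject * (1.0 + jitter), 40.0, 250.0))
        hrs.append(hr_k)
        times.append(times[-1] + 60.0 / hr_k)
    times = np.asarray(times)
    bounds = np.round(times * fs).astype(np.int64)
    keep = np.flatnonzero(np.diff(bounds) >= 4)  # guard against duplicates
    bounds = np.concatenate([bounds[keep], bounds[-1:]])
    hrs = np.asarray(hrs)[keep]
    n_beats = len(bounds) - 1
    n50 = int(bounds[-1]) + 1
    na = int(round((n50 - 1) * fsa / fs)) + 1

    t50 = np.arange(n50) / fs
    ta = np.arange(na) / fsa

    # --- latent slow traces -------------------------------------------
    drift = _slow_drift(ta, params.icp_drift_mmHg, rng)
    icp_slow = target_icp + drift
    map_slow = (
        params.map_base
        + params.map_slope * icp_slow
        + _slow_noise(ta, params.map_noise_sd, rng)
    )
    icp_slow_50 = np.interp(t50, ta, icp_slow)

    # --- per-beat templates -------------------------------------------
    beat_icp = np.empty(n_beats)
    beat_sig50 = np.zeros(n50)  # unit-amplitude optical pulse train, 50 Hz
    icp_pulse_a = np.zeros(na)
    abp_pulse_a = np.zeros(na)
    cbf_a = np.zeros(na)
    templates: list[np.ndarray] = []
    n_outliers_expected = params.outlier_beat_rate * n_beats
    outliers = np.flatnonzero(rng.random(n_beats) < params.outlier_beat_rate)
    del n_outliers_expected

    for k in range(n_beats):
        b0, b1 = int(bounds[k]), int(bounds[k + 1])
        icp_k = float(np.clip(np.mean(icp_slow_50[b0 : b1 + 1]), 0.0, 60.0))
        beat_icp[k] = icp_k
        tk = np.linspace(0.0, 1.0, b1 - b0 + 1)
        tpl = _template_on_grid(tk, icp_k, params)
        templates.append(tpl)
        scale = 3.0 if k in outliers else 1.0
        beat_sig50[b0 : b1 + 1] = scale * tpl  # endpoints are 0: overlap-safe
        # aux-rate beat (2x sample count on the shared-boundary grid)
        a0, a1 = 2 * b0, 2 * b1
        if a1 < na:
            tka = np.linspace(0.0, 1.0, a1 - a0 + 1)
            tpla = _template_on_grid(tka, icp_k, params)
            icp_pulse_a[a0 : a1 + 1] = params.icp_pulse_mmHg * (tpla - tpla.mean())
            abp_pulse_a[a0 : a1 + 1] = params.abp_pulse_mmHg * (tpla - tpla.mean())
            cbf_a[a0 : a1 + 1] = scale * tpla

    # --- channels ------------------------------------------------------
    noise = params.noise_sd
    dhbo = params.amp_dhbo_uM * (beat_sig50 + noise * rng.standard_normal(n50))
    dhbt = params.amp_dhbt_uM * (beat_sig50 + noise * rng.standard_normal(n50))
    cbf = params.amp_cbf * (cbf_a + noise * rng.standard_normal(na))
    icp_trace = icp_slow + icp_pulse_a
    abp_trace = map_slow + abp_pulse_a

    # --- planted instability artifacts (shared across optical channels) --
    events: list[tuple[str, float, float]] = []
    n_art = rng.poisson(params.artifact_rate_per_h * params.trial_duration_s / 3600.0)
    for _ in range(n_art):
        kind = "step" if rng.random() < 0.5 else "spike"
        if kind == "step":
            dur = rng.uniform(1.0, 3.0)
            start = rng.uniform(0.0, max(t50[-1] - dur, 0.0))
            sl50 = slice(int(start * fs), int((start + dur) * fs))
            sla = slice(int(start * fsa), int((start + dur) * fsa))
            mag = rng.choice([-1.0, 1.0]) * rng.uniform(8.0, 15.0)
            dhbo[sl50] += mag * params.amp_dhbo_uM
            dhbt[sl50] += mag * params.amp_dhbt_uM
            cbf[sla] += mag * params.amp_cbf
            events.append(("step", start, start + dur))
        else:
            start = rng.uniform(0.0, t50[-1])
            i50 = min(int(start * fs), n50 - 1)
            ia = min(int(start * fsa), na - 1)
            mag = rng.choice([-1.0, 1.0]) * rng.uniform(8.0, 15.0)
            dhbo[i50] += mag * params.amp_dhbo_uM
            dhbt[i50] += mag * params.amp_dhbt_uM
            cbf[ia] += mag * params.amp_cbf
            events.append(("spike", start, start + 1.0 / fs))

    key = f"{subject_id}/{trial_id}"
    gt.beat_bounds[key] = bounds
    gt.templates[key] = templates
    gt.beat_icp[key] = beat_icp
    gt.beat_hr[key] = hrs
    gt.true_icp[key] = icp_slow
    gt.true_map[key] = map_slow
    gt.artifacts[key] = events
    gt.outlier_beats[key] = outliers

    channels = {
        "dHbO": Channel(dhbo, fs, "dHbO", "uM"),
        "dHbT": Channel(dhbt, fs, "dHbT", "uM"),
        "CBF": Channel(cbf, fsa, "CBF", "a.u."),
        "ABP": Channel(abp_trace, fsa, "ABP", "mmHg"),
        "ICP": Channel(icp_trace, fsa, "ICP", "mmHg"),
    }
    # R peaks: one event per beat, at the beat-onset diastole, on the
    # aux (100-Hz) grid as the hardware event train would be.
    rpeaks = Channel(2 * bounds[:-1], fsa, "Rpeaks")
    return Trial(trial_id, target_icp, channels, rpeaks)


def make_subject(
    params: GeneratorParams, subject_index: int
) -> tuple[Recording, GroundTruth]:
    """Generate one subject's stepped-ICP trials with aligned ground truth.

    Deterministic in ``(params, subject_index)``: the per-subject stream is
    spawned from ``params.rng_seed`` and the subject index.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.rng_seed), int(subject_index)])
    )
    subject_id = f"S{subject_index:02d}"
    lo, hi = params.heart_rate_bpm
    hr_subject = float(rng.uniform(lo, hi))
    gt = GroundTruth(subject_id=subject_id)
    trials = [
        _make_trial(params, subject_id, i, tgt, hr_subject, rng, gt)
        for i, tgt in enumerate(params.trial_targets())
    ]
    rec = Recording(
        subject_id,
        trials,
        meta={
            "hr_bpm": hr_subject,
            "fs_nirs": params.fs_nirs,
            "fs_aux": params.fs_aux,
            "rng_seed": params.rng_seed,
            "subject_index": subject_index,
        },
    )
    return rec, gt


def make_cohort(params: GeneratorParams) -> list[tuple[Recording, GroundTruth]]:
    """All subjects of the cohort, one deterministic stream each."""
    return [make_subject(params, i) for i in range(params.n_subjects)]


def forward_mbll(
    dhbo: np.ndarray,
    dhb: np.ndarray,
    model: ExtinctionModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL: hemoglobin-concentration changes (uM) -> dOD traces.

    ``dOD_l = (eps_HbO,l * dHbO + eps_Hb,l * dHb) * distance * DPF_l``
    for the 690- and 830-nm rows of the extinction model.  Exists for
    round-trip testing of :func:`pulseicp.hemo.mbll_invert`.
    """
    a = model.system_matrix()
    dod = a @ np.vstack([np.asarray(dhbo, float), np.asarray(dhb, float)])
    return dod[0], dod[1]


def make_ekg(
    duration_s: float,
    hr: float,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Channel, np.ndarray]:
    """Synthetic EKG from a periodic PQRST-like template plus noise.

    Returns the channel and the true R-peak sample indices.  ``noise_sd``
    is in units of the R amplitude (1.0).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    period = 60.0 / hr
    phase = np.mod(t, period) / period  # 0..1 within each beat
    def bump(center, width, amp):
        return amp * np.exp(-0.5 * ((phase - center) / width) ** 2)
    ekg = (
        bump(0.25, 0.006, 1.0)      # R
        + bump(0.23, 0.008, -0.15)  # Q
        + bump(0.27, 0.008, -0.25)  # S
        + bump(0.45, 0.04, 0.2)     # T
        + bump(0.15, 0.025, 0.1)    # P
    )
    ekg += noise_sd * rng.standard_normal(n)
    beat_starts = np.arange(0, duration_s, period)
    r_times = beat_starts + 0.25 * period
    r_idx = np.round(r_times * fs).astype(np.int64)
    r_idx = r_idx[r_idx < n]
    return Channel(ekg, fs, "EKG", "a.u."), r_idx
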