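"""Seeded multichannel physiological signal simulator.

Generates recordings that emulate a laboratory stress-induction protocol:
each subject passes through baseline (neutral reading), amusement (funny
videos) and stress (Trier-Social-Stress-style tasks) segments while six
channels are sampled — chest ECG/EMG/EDA/respiration at a high rate and
wrist EDA/temperature at a low rate.  The condition-dependent defaults are
centred on physiology reported experimentally for stress: mean heart rate
78.45 bpm at baseline vs 95.54 bpm under stress, reduced beat-to-beat
variability (RMSSD ~40 ms -> ~30 ms), elevated skin conductance level and
response rate, higher trapezius EMG amplitude, faster respiration, and
lower wrist temperature.

Only beat timing matters downstream, so the ECG is a stylised train of
80 ms biphasic QRS pulses; no P/T-wave morphology is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import CHANNEL_NAMES, StressReportError

CONDITIONS: tuple[str, ...] = ("baseline", "amusement", "stress")

#: Default per-channel sampling rates (Hz): chest channels high-rate,
#: wrist channels low-rate, mirroring chest-strap vs wristband hardware.
DEFAULT_FS: dict[str, float] = {
    "ecg": 256.0,
    "emg_chest": 256.0,
    "eda_chest": 256.0,
    "resp": 256.0,
    "eda_wrist": 4.0,
    "temp_wrist": 4.0,
}

# Condition-dependent generator centres.  Heart-rate mean/variability come
# from published stress-experiment tables (78.45/95.54 bpm); the SDNN
# values are chosen so that with independent Gaussian beat intervals
# RMSSD = sqrt(2)*SDNN lands on the published 40 ms (no stress) vs 30 ms
# (stress), which also places pNN50 near its published 22.9% vs 7.4%.
# Amusement is modelled at baseline levels.
PARAM_CENTERS: dict[str, dict[str, float]] = {
    "hr_mean_bpm": {"baseline": 78.45, "amusement": 78.45, "stress": 95.54},
    "sdnn_ms": {"baseline": 28.28, "amusement": 28.28, "stress": 21.21},
    "scl_level_uS": {"baseline": 3.7, "amusement": 3.7, "stress": 10.7},
    "scr_rate_per_min": {"baseline": 2.0, "amusement": 2.0, "stress": 8.0},
    "emg_rms_mV": {"baseline": 0.02, "amusement": 0.02, "stress": 0.06},
    "resp_rate_brpm": {"baseline": 14.0, "amusement": 14.0, "stress": 19.0},
    "wrist_temp_C": {"baseline": 34.9, "amusement": 34.9, "stress": 31.7},
}

# Between-subject standard deviations applied as a single subject-level
# offset per quantity (all conditions shift together, so every subject
# keeps the population effect direction).  Kept moderate relative to the
# within-subject wander below, so that a reference interval learned on
# one group of subjects retains close to nominal coverage on new
# subjects; the published population spreads additionally fold in
# measurement-protocol variation that the simulator does not model.
PARAM_JITTER_SD: dict[str, float] = {
    "hr_mean_bpm": 1.5,
    "sdnn_ms": 1.5,
    "scl_level_uS": 0.3,
    "scr_rate_per_min": 0.3,
    "emg_rms_mV": 0.0015,
    "resp_rate_brpm": 0.5,
    "wrist_temp_C": 0.25,
}

# Slow within-subject physiological wander: each parameter is modulated
# by a zero-mean sinusoid (additive in the parameter's units or
# multiplicative as a fraction) with a parameter-specific period, so
# window-level values spread realistically around the condition mean
# while segment means stay on the condition centres.
MODULATION: dict[str, tuple[str, float, float]] = {
    # name: (mode, depth, period_s)
    "hr_mean_bpm": ("add", 4.0, 311.0),
    "sdnn_ms": ("mul", 0.20, 389.0),
    "scl_level_uS": ("mul", 0.20, 433.0),
    "scr_rate_per_min": ("mul", 0.30, 471.0),
    "emg_rms_mV": ("mul", 0.20, 521.0),
    "resp_rate_brpm": ("add", 1.5, 571.0),
    "wrist_temp_C": ("add", 0.7, 613.0),
}

DEFAULT_NOISE: dict[str, float] = {
    "ecg": 0.01,        # mV additive white noise
    "eda_chest": 0.01,  # uS
    "eda_wrist": 0.01,
    "resp": 0.02,       # arbitrary units on a unit-amplitude sinusoid
    "temp_wrist": 0.01, # degC
}

#: Effect directions the generator imposes on strongly shifted features,
#: expressed in the vocabulary of the interval tables.  This is the
#: ground truth that downstream direction/p-value/concordance checks are
#: measured against; features the generator leaves (nearly) unchanged
#: (e.g. mu_EMG, sigma_RespRate, sigma_WristTemp, MCV_NN, Peaks_EMG) are
#: deliberately absent.
STRONG_EFFECT_DIRECTIONS: dict[str, str] = {
    "mu_HR": "increases_with_stress",
    "Max_HR": "increases_with_stress",
    "Min_HR": "increases_with_stress",
    "mu_NN": "decreases_with_stress",
    "sigma_NN": "decreases_with_stress",
    "Mad_NN": "decreases_with_stress",
    "Med_NN": "decreases_with_stress",
    "RMSSD_NN": "decreases_with_stress",
    "pNN20": "decreases_with_stress",
    "pNN50": "decreases_with_stress",
    "sigma_EMG": "increases_with_stress",
    "Max_EMG": "increases_with_stress",
    "Min_EMG": "decreases_with_stress",
    "RMS_EMG": "increases_with_stress",
    "RMS50P_EMG": "increases_with_stress",
    "RMS90P_EMG": "increases_with_stress",
    "mu_WristEDA": "increases_with_stress",
    "sigma_WristEDA": "increases_with_stress",
    "Max_WristEDA": "increases_with_stress",
    "Min_WristEDA": "increases_with_stress",
    "mu_ChestEDA": "increases_with_stress",
    "sigma_ChestEDA": "increases_with_stress",
    "Max_ChestEDA": "increases_with_stress",
    "Min_ChestEDA": "increases_with_stress",
    "mu_ChestSCL": "increases_with_stress",
    "sigma_ChestSCR": "increases_with_stress",
    "mu_RespRate": "increases_with_stress",
    "Max_RespRate": "increases_with_stress",
    "Min_RespRate": "increases_with_stress",
    "mu_WristTemp": "decreases_with_stress",
    "Max_WristTemp": "decreases_with_stress",
    "Min_WristTemp": "decreases_with_stress",
}

Schedule = list[tuple[str, float]]


def wesad_like_schedule() -> Schedule:
    """Protocol schedule emulating the public chest+wrist stress dataset:
    20 min baseline, 6.5 min amusement, 10 min stress."""
    return [("baseline", 1200.0), ("amusement", 390.0), ("stress", 600.0)]


@dataclass
class SubjectParams:
    """Condition-dependent physiological parameters for one subject.

    Each mapping is keyed by condition name; see :data:`PARAM_CENTERS`
    for units and population centres.
    """

    subject_id: str
    hr_mean_bpm: dict[str, float]
    sdnn_ms: dict[str, float]
    scl_level_uS: dict[str, float]
    scr_rate_per_min: dict[str, float]
    emg_rms_mV: dict[str, float]
    resp_rate_brpm: dict[str, float]
    wrist_temp_C: dict[str, float]
    noise: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    #: depth of the slow within-subject wander per parameter (same keys as
    #: :data:`MODULATION`; 0 disables the wander for that parameter)
    modulation: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in MODULATION.items()}
    )

    def validate(self) -> None:
        for cond in CONDITIONS:
            if not 30.0 <= self.hr_mean_bpm[cond] <= 220.0:
                raise StressReportError(
                    f"hr_mean_bpm[{cond}]={self.hr_mean_bpm[cond]} outside [30, 220]"
                )
            if not 4.0 <= self.resp_rate_brpm[cond] <= 60.0:
                raise StressReportError(
                    f"resp_rate_brpm[{cond}]={self.resp_rate_brpm[cond]} outside [4, 60]"
                )
            for name in ("sdnn_ms", "scl_level_uS", "scr_rate_per_min", "emg_rms_mV"):
                if getattr(self, name)[cond] < 0:
                    raise StressReportError(f"{name}[{cond}] must be >= 0")


@dataclass
class Recording:
    """Raw multichannel signals, sampling rates and condition labels for
    one subject.  ``channels`` maps channel name to ``(samples, fs)``;
    ``label_intervals`` is a list of half-open ``(start_s, end_s,
    condition)`` intervals tiling the full duration."""

    subject_id: str
    channels: dict[str, tuple[np.ndarray, float]]
    label_intervals: list[tuple[float, float, str]]

    @property
    def duration_s(self) -> float:
        return float(self.label_intervals[-1][1]) if self.label_intervals else 0.0

    def validate(self) -> None:
        missing = set(CHANNEL_NAMES) - set(self.channels)
        if missing:
            raise StressReportError(f"missing channels: {sorted(missing)}")
        dur = self.duration_s
        for name, (samples, fs) in self.channels.items():
            if fs <= 0:
                raise StressReportError(f"channel {name!r}: fs must be > 0")
            if abs(len(samples) / fs - dur) > 1.0 / fs + 1e-9:
                raise StressReportError(
                    f"channel {name!r} covers {len(samples) / fs:.3f}s, "
                    f"labels cover {dur:.3f}s"
                )
        prev_end = 0.0
        for start, end, cond in self.label_intervals:
            if cond not in CONDITIONS:
                raise StressReportError(f"unknown condition {cond!r}")
            if start > prev_end + 1e-9:
                raise StressReportError(
                    f"label gap between {prev_end}s and {start}s"
                )
            if start < prev_end - 1e-9:
                raise StressReportError(
                    f"label overlap at {start}s (previous interval ends {prev_end}s)"
                )
            if end <= start:
                raise StressReportError(f"empty label interval at {start}s")
            prev_end = end


def default_subject_params(
    seed: int, subject_id: str = "S0", jitter_scale: float = 1.0
) -> SubjectParams:
    """Draw one subject's parameters around the published stress-physiology
    centres.

    ``jitter_scale`` multiplies the between-subject standard deviations;
    0 returns the centres exactly.  Same seed, same parameters.
    """
    rng = np.random.default_rng(seed)
    fields = {}
    for name, centers in PARAM_CENTERS.items():
        offset = jitter_scale * PARAM_JITTER_SD[name] * rng.standard_normal()
        values = {}
        for cond in CONDITIONS:
            v = centers[cond] + offset
            # keep strictly positive quantities away from zero
            if name not in ("wrist_temp_C",):
                v = max(v, 0.2 * centers[cond])
            values[cond] = float(v)
        fields[name] = values
    return SubjectParams(subject_id=subject_id, **fields)


def _check_schedule(schedule: Schedule) -> list[tuple[float, float, str]]:
    if not schedule:
        raise StressReportError("schedule must contain at least one segment")
    intervals = []
    t = 0.0
    for cond, dur in schedule:
        if cond not in CONDITIONS:
            raise StressReportError(f"unknown condition {cond!r}")
        if dur <= 0:
            raise StressReportError("segment durations must be > 0")
        intervals.append((t, t + float(dur), cond))
        t += float(dur)
    return intervals


def _condition_at(intervals: list[tuple[float, float, str]], t: float) -> str:
    for start, end, cond in intervals:
        if start <= t < end:
            return cond
    return intervals[-1][2]


def _modulated(
    params: SubjectParams, name: str, cond: str, t, phase: float
):
    """Parameter value at time(s) ``t``: condition centre plus the slow
    zero-mean sinusoidal wander."""
    base = getattr(params, name)[cond]
    mode, _, period = MODULATION[name]
    depth = params.modulation.get(name, 0.0)
    wave = np.sin(2.0 * np.pi * np.asarray(t) / period + phase)
    if mode == "add":
        return base + depth * wave
    return base * (1.0 + depth * wave)


def _modulated_series(
    params: SubjectParams,
    name: str,
    intervals: list[tuple[float, float, str]],
    t: np.ndarray,
    phase: float,
) -> np.ndarray:
    out = np.empty(len(t))
    for start, end, cond in intervals:
        mask = (t >= start) & (t < end)
        out[mask] = _modulated(params, name, cond, t[mask], phase)
    return out


def _qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """80 ms biphasic pulse: 40 ms triangular R wave of amplitude 1 mV
    followed by a 40 ms shallow negative lobe.  Returns (template, index
    of the apex within the template)."""
    n_half = max(1, int(round(0.02 * fs)))   # 20 ms rise / fall
    n_neg = max(1, int(round(0.04 * fs)))
    rise = np.linspace(0.0, 1.0, n_half, endpoint=False)
    fall = np.linspace(1.0, 0.0, n_half, endpoint=False)
    neg = -0.25 * np.sin(np.linspace(0.0, np.pi, n_neg))
    template = np.concatenate([rise, fall, neg])
    return template, n_half  # apex is the first sample of `fall` (value 1.0)


def _beat_times(
    params: SubjectParams,
    intervals: list[tuple[float, float, str]],
    duration: float,
    rng: np.random.Generator,
    phases: dict[str, float],
) -> np.ndarray:
    times = []
    t = 0.3  # first beat shortly after recording start
    while t < duration - 0.1:
        times.append(t)
        cond = _condition_at(intervals, t)
        hr = float(_modulated(params, "hr_mean_bpm", cond, t, phases["hr_mean_bpm"]))
        sdnn = float(_modulated(params, "sdnn_ms", cond, t, phases["sdnn_ms"]))
        nn_ms = 60000.0 / hr + sdnn * rng.standard_normal()
        nn_ms = max(nn_ms, 300.0)
        t += nn_ms / 1000.0
    return np.asarray(times)


def _scr_kernel(fs: float, amplitude: float) -> np.ndarray:
    """Electrodermal response shape: 1 s linear rise, exponential decay
    with tau = 4 s (truncated at 8 tau)."""
    n_rise = max(1, int(round(1.0 * fs)))
    t_decay = np.arange(0, int(round(32.0 * fs))) / fs
    rise = amplitude * np.linspace(0.0, 1.0, n_rise, endpoint=False)
    decay = amplitude * np.exp(-t_decay / 4.0)
    return np.concatenate([rise, decay])


def _eda_channel(
    params: SubjectParams,
    level_scale: float,
    intervals: list[tuple[float, float, str]],
    duration: float,
    fs: float,
    scr_amp: float,
    noise_sd: float,
    rng: np.random.Generator,
    phases: dict[str, float],
) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = level_scale * _modulated_series(
        params, "scl_level_uS", intervals, t, phases["scl_level_uS"]
    )
    # Poisson-timed phasic responses per condition segment
    for start, end, cond in intervals:
        rate = params.scr_rate_per_min[cond]
        lam = rate / 60.0 * (end - start)
        n_events = rng.poisson(lam)
        event_times = np.sort(rng.uniform(start, end, size=n_events))
        for et in event_times:
            scale = float(
                _modulated(params, "scr_rate_per_min", cond, et,
                           phases["scr_rate_per_min"])
            ) / max(rate, 1e-9)
            amp = scr_amp * scale + 0.1 * scr_amp * rng.standard_normal()
            amp = max(amp, 0.05 * scr_amp)
            kernel = _scr_kernel(fs, amp)
            i0 = int(round(et * fs))
            i1 = min(i0 + len(kernel), n)
            if i0 < n:
                x[i0:i1] += kernel[: i1 - i0]
    x += noise_sd * rng.standard_normal(n)
    return x


def simulate_subject(
    params: SubjectParams,
    schedule: Schedule,
    fs_map: dict[str, float] | None = None,
    seed: int = 0,
) -> Recording:
    """Simulate one subject's six-channel recording under ``schedule``.

    Channel models: ECG = stylised QRS train with Gaussian beat-to-beat
    intervals (mean 60000/HR ms, sd SDNN ms per active condition); chest
    and wrist EDA = tonic level plus Poisson-timed phasic responses; EMG =
    zero-mean Gaussian noise at the condition's RMS amplitude;
    respiration = unit sinusoid at the condition's rate; wrist
    temperature = condition level plus slow drift.  Condition transitions
    are instantaneous.  Bit-identical output for identical inputs.
    """
    params.validate()
    intervals = _check_schedule(schedule)
    fs_map = dict(DEFAULT_FS if fs_map is None else fs_map)
    missing = set(CHANNEL_NAMES) - set(fs_map)
    if missing:
        raise StressReportError(f"fs_map missing channels: {sorted(missing)}")
    if fs_map["ecg"] < 100.0:
        raise StressReportError(
            f"ECG sampling rate {fs_map['ecg']} Hz is below the 100 Hz "
            "minimum needed to resolve QRS timing"
        )
    duration = intervals[-1][1]
    streams = np.random.SeedSequence(seed).spawn(7)
    rngs = {name: np.random.default_rng(s) for name, s in zip(CHANNEL_NAMES, streams)}
    phase_rng = np.random.default_rng(streams[6])
    phases = {name: float(phase_rng.uniform(0.0, 2.0 * np.pi)) for name in MODULATION}

    channels: dict[str, tuple[np.ndarray, float]] = {}

    # --- ECG ---
    fs = fs_map["ecg"]
    n = int(round(duration * fs))
    rng = rngs["ecg"]
    ecg = params.noise.get("ecg", 0.0) * rng.standard_normal(n)
    template, apex = _qrs_template(fs)
    for bt in _beat_times(params, intervals, duration, rng, phases):
        i_apex = int(round(bt * fs))
        i0 = i_apex - apex
        j0, j1 = max(i0, 0), min(i0 + len(template), n)
        if j1 > j0:
            ecg[j0:j1] += template[j0 - i0 : j1 - i0]
    channels["ecg"] = (ecg, fs)

    # --- chest EMG ---
    fs = fs_map["emg_chest"]
    n = int(round(duration * fs))
    rng = rngs["emg_chest"]
    t = np.arange(n) / fs
    sd_t = _modulated_series(params, "emg_rms_mV", intervals, t, phases["emg_rms_mV"])
    emg = sd_t * rng.standard_normal(n)
    channels["emg_chest"] = (emg, fs)

    # --- EDA (chest high-rate, wrist low-rate at attenuated level) ---
    channels["eda_chest"] = (
        _eda_channel(
            params, 1.0, intervals, duration, fs_map["eda_chest"], scr_amp=0.3,
            noise_sd=params.noise.get("eda_chest", 0.0), rng=rngs["eda_chest"],
            phases=phases,
        ),
        fs_map["eda_chest"],
    )
    channels["eda_wrist"] = (
        _eda_channel(
            params, 0.3, intervals, duration, fs_map["eda_wrist"], scr_amp=0.15,
            noise_sd=params.noise.get("eda_wrist", 0.0), rng=rngs["eda_wrist"],
            phases=phases,
        ),
        fs_map["eda_wrist"],
    )

    # --- respiration: continuous-phase sinusoid ---
    fs = fs_map["resp"]
    n = int(round(duration * fs))
    rng = rngs["resp"]
    t = np.arange(n) / fs
    freq = (
        _modulated_series(params, "resp_rate_brpm", intervals, t,
                          phases["resp_rate_brpm"])
        / 60.0
    )
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    resp = np.sin(phase) + params.noise.get("resp", 0.0) * rng.standard_normal(n)
    channels["resp"] = (resp, fs)

    # --- wrist temperature: condition level + slow wander ---
    fs = fs_map["temp_wrist"]
    n = int(round(duration * fs))
    rng = rngs["temp_wrist"]
    t = np.arange(n) / fs
    temp = _modulated_series(params, "wrist_temp_C", intervals, t,
                             phases["wrist_temp_C"])
    temp += params.noise.get("temp_wrist", 0.0) * rng.standard_normal(n)
    channels["temp_wrist"] = (temp, fs)

    rec = Recording(
        subject_id=params.subject_id,
        channels=channels,
        label_intervals=intervals,
    )
    rec.validate()
    return rec


def simulate_cohort(
    n_subjects: int,
    schedule: Schedule | None = None,
    seed: int = 0,
    jitter_scale: float = 1.0,
    fs_map: dict[str, float] | None = None,
) -> list[Recording]:
    """Simulate ``n_subjects`` independent subjects under a shared protocol
    schedule (default: the 20 min / 6.5 min / 10 min laboratory protocol)."""
    if n_subjects < 1:
        raise StressReportError("n_subjects must be >= 1")
    if schedule is None:
        schedule = wesad_like_schedule()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    recordings = []
    for i, child in enumerate(children):
        param_seed, signal_seed = child.spawn(2)
        params = default_subject_params(
            seed=int(param_seed.generate_state(1)[0] % (2**31)),
            subject_id=f"S{i:02d}",
            jitter_scale=jitter_scale,
        )
        rec = simulate_subject(
            params,
            schedule,
            fs_map=fs_map,
            seed=int(signal_seed.generate_state(1)[0] % (2**31)),
        )
        recordings.append(rec)
    return recordings
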