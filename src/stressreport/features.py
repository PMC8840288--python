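"""Window segmentation and extraction of the 42 physiological features.

A recording is cut into fixed-length windows (default 90 s, stride 30 s)
that never straddle a condition boundary; each window yields one vector of
42 named features in the canonical registry order: heart-rate / HRV
statistics from detected R-peaks, time- and frequency-domain variability,
surface-EMG amplitude statistics, tonic/phasic electrodermal measures for
both sites, respiration-rate statistics from breath peaks, and wrist
temperature statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .registry import (
    FEATURE_NAMES,
    N_FEATURES,
    UNIT_OF,
    FeatureExtractionError,
    InsufficientBeatsError,
    StressReportError,
)
from .synthetic import Recording

META_COLUMNS = ("subject_id", "start_s", "duration_s", "condition", "y")

#: NN-interval artifact rejection: physiological range and the maximum
#: fractional jump from the previously accepted interval.
NN_RANGE_MS = (300.0, 2000.0)
NN_MAX_JUMP = 0.25


@dataclass(frozen=True)
class Window:
    """A labelled analysis window lying inside one condition interval."""

    subject_id: str
    start_s: float
    duration_s: float
    condition: str

    @property
    def y(self) -> int:
        return 1 if self.condition == "stress" else 0


def segment_windows(
    rec: Recording, duration_s: float = 90.0, step_s: float = 30.0
) -> list[Window]:
    """Maximal placement of [start, start+duration) windows with stride
    ``step_s`` that fit entirely inside a single condition interval.
    Windows from baseline and amusement are labelled no-stress (y=0)."""
    if duration_s <= 0 or step_s <= 0:
        raise StressReportError("duration_s and step_s must be > 0")
    windows = []
    for start, end, cond in rec.label_intervals:
        s = start
        while s + duration_s <= end + 1e-9:
            windows.append(Window(rec.subject_id, float(s), float(duration_s), cond))
            s += step_s
    return windows


# ---------------------------------------------------------------------------
# ECG / HRV


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak indices via amplitude thresholding with a 200 ms refractory
    constraint.

    Assumes wearable-grade ECG in which the R deflection dominates the
    window (true for the bundled simulator); an all-zero or flat signal
    yields no peaks.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100.0:
        raise StressReportError(f"ECG fs {fs} Hz < 100 Hz minimum")
    if len(ecg) < 2 * fs:
        raise StressReportError("ECG segment shorter than 2 s")
    x = ecg - np.median(ecg)
    peak_height = 0.5 * np.max(x) if np.max(x) > 0 else np.inf
    if not np.isfinite(peak_height) or np.std(x) == 0:
        return np.asarray([], dtype=int)
    peaks, _ = sps.find_peaks(x, height=peak_height, distance=max(1, int(round(0.2 * fs))))
    return peaks.astype(int)


def nn_intervals(peaks: np.ndarray, fs: float) -> np.ndarray:
    """Beat-to-beat (NN) intervals in ms after artifact rejection.

    Intervals outside [300, 2000] ms, or differing by more than 25% from
    the previously accepted interval, are dropped (ectopy / detection
    artifacts).  Raises :class:`InsufficientBeatsError` when fewer than
    three intervals survive.
    """
    peaks = np.asarray(peaks)
    if len(peaks) < 4:
        raise InsufficientBeatsError(f"only {len(peaks)} peaks detected; need >= 4")
    raw = np.diff(peaks) * 1000.0 / fs
    accepted: list[float] = []
    for v in raw:
        if not NN_RANGE_MS[0] <= v <= NN_RANGE_MS[1]:
            continue
        if accepted and abs(v - accepted[-1]) / accepted[-1] > NN_MAX_JUMP:
            continue
        accepted.append(float(v))
    if len(accepted) < 3:
        raise InsufficientBeatsError(
            f"only {len(accepted)} NN intervals survive artifact rejection"
        )
    return np.asarray(accepted)


def hrv_time_features(nn: np.ndarray) -> dict[str, float]:
    """Time-domain HRV statistics from an NN series (ms)."""
    nn = np.asarray(nn, dtype=float)
    if len(nn) < 3:
        raise InsufficientBeatsError("need >= 3 NN intervals")
    hr = 60000.0 / nn
    dnn = np.diff(nn)
    med = float(np.median(nn))
    mad = float(np.median(np.abs(nn - med)))
    return {
        "mu_HR": float(np.mean(hr)),
        "sigma_HR": float(np.std(hr, ddof=1)),
        "Max_HR": float(np.max(hr)),
        "Min_HR": float(np.min(hr)),
        "mu_NN": float(np.mean(np.abs(nn))),
        "sigma_NN": float(np.std(nn, ddof=1)),
        "Mad_NN": mad,
        "Med_NN": med,
        "MCV_NN": mad / med if med != 0 else 0.0,
        "RMSSD_NN": float(np.sqrt(np.mean(dnn**2))),
        "pNN20": 100.0 * float(np.mean(np.abs(dnn) > 20.0)),
        "pNN50": 100.0 * float(np.mean(np.abs(dnn) > 50.0)),
    }


def hrv_frequency_features(nn: np.ndarray, beat_times_s: np.ndarray) -> dict[str, float]:
    """LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) band powers in ms^2.

    The NN series is linearly resampled to a uniform 4 Hz grid at the
    times of the interval-closing beats and the power spectral density is
    estimated with Welch's method.
    """
    nn = np.asarray(nn, dtype=float)
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if len(beat_times_s) != len(nn):
        raise StressReportError("beat_times_s must align with nn")
    span = beat_times_s[-1] - beat_times_s[0]
    if span < 60.0:
        raise InsufficientBeatsError(f"beat span {span:.1f}s < 60s needed for LF power")
    fs_interp = 4.0
    grid = np.arange(beat_times_s[0], beat_times_s[-1], 1.0 / fs_interp)
    series = np.interp(grid, beat_times_s, nn)
    nperseg = min(256, len(series))
    freqs, psd = sps.welch(series, fs=fs_interp, nperseg=nperseg, detrend="constant")
    out = {}
    for name, lo, hi in (("LF_HRV", 0.04, 0.15), ("HF_HRV", 0.15, 0.40)):
        band = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.trapezoid(psd[band], freqs[band])) if band.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# EMG


def emg_features(emg: np.ndarray, fs: float) -> dict[str, float]:
    """Amplitude statistics of the surface EMG.

    RMS features use the mean-removed signal; RMS50P/RMS90P are the 50th
    and 90th percentiles of rank-ordered RMS values over non-overlapping
    1 s sub-windows.  Peaks_EMG counts local maxima above mean + 2 sd.
    """
    emg = np.asarray(emg, dtype=float)
    if fs <= 0:
        raise StressReportError("fs must be > 0")
    if len(emg) < 10 * fs:
        raise StressReportError("EMG segment shorter than 10 s")
    mean = float(np.mean(emg))
    sd = float(np.std(emg, ddof=1))
    centered = emg - mean
    n_sub = int(len(emg) // int(round(fs)))
    if n_sub < 2:
        raise StressReportError("EMG segment shorter than two 1 s sub-windows")
    sub = centered[: n_sub * int(round(fs))].reshape(n_sub, -1)
    sub_rms = np.sqrt(np.mean(sub**2, axis=1))
    peaks, _ = sps.find_peaks(emg, height=mean + 2.0 * sd)
    return {
        "mu_EMG": mean,
        "sigma_EMG": sd,
        "Max_EMG": float(np.max(emg)),
        "Min_EMG": float(np.min(emg)),
        "Peaks_EMG": float(len(peaks)),
        "RMS_EMG": float(np.sqrt(np.mean(centered**2))),
        "RMS50P_EMG": float(np.percentile(sub_rms, 50)),
        "RMS90P_EMG": float(np.percentile(sub_rms, 90)),
    }


# ---------------------------------------------------------------------------
# EDA


def eda_features(eda: np.ndarray, fs: float, site: str) -> dict[str, float]:
    """Electrodermal statistics for one site.

    Both sites get mean / sd / max / min of the raw conductance.  For the
    chest site the tonic skin-conductance level (SCL) is the 0.05 Hz
    low-pass component and the phasic response (SCR) is the residual;
    their means and standard deviations are reported in addition.
    """
    if site not in ("wrist", "chest"):
        raise StressReportError(f"unknown EDA site {site!r}")
    if fs <= 0:
        raise StressReportError("fs must be > 0")
    eda = np.asarray(eda, dtype=float)
    if len(eda) < 10 * fs:
        raise StressReportError("EDA segment shorter than 10 s")
    prefix = "Wrist" if site == "wrist" else "Chest"
    out = {
        f"mu_{prefix}EDA": float(np.mean(eda)),
        f"sigma_{prefix}EDA": float(np.std(eda, ddof=1)),
        f"Max_{prefix}EDA": float(np.max(eda)),
        f"Min_{prefix}EDA": float(np.min(eda)),
    }
    if site == "chest":
        sos = sps.butter(2, 0.05, btype="low", fs=fs, output="sos")
        scl = sps.sosfiltfilt(sos, eda)
        scr = eda - scl
        out.update(
            {
                "mu_ChestSCL": float(np.mean(scl)),
                "sigma_ChestSCL": float(np.std(scl, ddof=1)),
                "mu_ChestSCR": float(np.mean(scr)),
                "sigma_ChestSCR": float(np.std(scr, ddof=1)),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Respiration and temperature


def resp_features(resp: np.ndarray, fs: float) -> dict[str, float]:
    """Respiration-rate statistics from band-passed (0.1-0.5 Hz) breath
    peaks; instantaneous rate is 60 / inter-breath interval."""
    resp = np.asarray(resp, dtype=float)
    if fs <= 0:
        raise StressReportError("fs must be > 0")
    if len(resp) < 30 * fs:
        raise StressReportError("respiration segment shorter than 30 s")
    sos = sps.butter(2, [0.1, 0.5], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, resp)
    sd = float(np.std(filtered))
    if sd == 0:
        raise InsufficientBeatsError("no respiratory oscillation detected")
    peaks, _ = sps.find_peaks(
        filtered, distance=max(1, int(round(fs))), prominence=0.5 * sd
    )
    if len(peaks) < 3:
        raise InsufficientBeatsError(f"only {len(peaks)} breaths detected; need >= 3")
    rates = 60.0 / (np.diff(peaks) / fs)
    return {
        "mu_RespRate": float(np.mean(rates)),
        "sigma_RespRate": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
        "Max_RespRate": float(np.max(rates)),
        "Min_RespRate": float(np.min(rates)),
    }


def temp_features(temp: np.ndarray) -> dict[str, float]:
    temp = np.asarray(temp, dtype=float)
    if len(temp) == 0:
        raise StressReportError("empty temperature segment")
    return {
        "mu_WristTemp": float(np.mean(temp)),
        "sigma_WristTemp": float(np.std(temp, ddof=1)) if len(temp) > 1 else 0.0,
        "Max_WristTemp": float(np.max(temp)),
        "Min_WristTemp": float(np.min(temp)),
    }


# ---------------------------------------------------------------------------
# Assembly


def _slice(rec: Recording, channel: str, window: Window) -> tuple[np.ndarray, float]:
    samples, fs = rec.channels[channel]
    i0 = int(round(window.start_s * fs))
    i1 = int(round((window.start_s + window.duration_s) * fs))
    if i0 < 0 or i1 > len(samples):
        raise StressReportError(
            f"window [{window.start_s}, {window.start_s + window.duration_s})s "
            f"outside channel {channel!r}"
        )
    return samples[i0:i1], fs


def extract_features(rec: Recording, window: Window) -> dict[str, float]:
    """Concatenate the per-signal extractors into the canonical 42-feature
    vector for one window.  Extractor failures are re-raised with the
    window identified."""
    try:
        ecg, fs_ecg = _slice(rec, "ecg", window)
        peaks = detect_r_peaks(ecg, fs_ecg)
        nn = nn_intervals(peaks, fs_ecg)
        beat_times = peaks[1:] / fs_ecg  # interval-closing beats (pre-rejection grid)
        values = {}
        values.update(hrv_time_features(nn))
        values.update(
            hrv_frequency_features(np.diff(peaks) * 1000.0 / fs_ecg, beat_times)
        )
        values.update(emg_features(*_slice(rec, "emg_chest", window)))
        values.update(eda_features(*_slice(rec, "eda_wrist", window), site="wrist"))
        values.update(eda_features(*_slice(rec, "eda_chest", window), site="chest"))
        values.update(resp_features(*_slice(rec, "resp", window)))
        values.update(temp_features(_slice(rec, "temp_wrist", window)[0]))
    except StressReportError as err:
        raise FeatureExtractionError(
            f"subject {rec.subject_id}, window at {window.start_s}s: {err}"
        ) from err
    assert set(values) == set(FEATURE_NAMES), "feature registry mismatch"
    return {name: values[name] for name in FEATURE_NAMES}


@dataclass
class FeatureMatrix:
    """Windows x features table plus labels, backed by a DataFrame whose
    columns are ``META_COLUMNS`` followed by the 42 canonical features."""

    frame: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(UNIT_OF))

    def __post_init__(self) -> None:
        expected = list(META_COLUMNS) + list(FEATURE_NAMES)
        if list(self.frame.columns) != expected:
            raise StressReportError("FeatureMatrix columns do not match the registry")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.frame.loc[mask].reset_index(drop=True), dict(self.units))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path))


def extract_cohort_features(
    recordings: list[Recording], duration_s: float = 90.0, step_s: float = 30.0
) -> FeatureMatrix:
    """Segment and extract every recording into one feature matrix."""
    rows = []
    for rec in recordings:
        for window in segment_windows(rec, duration_s, step_s):
            values = extract_features(rec, window)
            row = {
                "subject_id": window.subject_id,
                "start_s": window.start_s,
                "duration_s": window.duration_s,
                "condition": window.condition,
                "y": window.y,
            }
            row.update(values)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    return FeatureMatrix(frame)
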