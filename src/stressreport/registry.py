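"""Canonical feature registry: the 42 physiological tests and their units.

The order below is the canonical column order of every feature matrix and
the row order of the rendered report: 14 ECG-derived features, 8 EMG, 12
EDA (4 wrist, 4 chest raw, 2 tonic SCL + 2 phasic SCR), 4 respiration, 4
wrist temperature.
"""

from __future__ import annotations

# (name, unit) pairs; "" marks a dimensionless quantity.
FEATURE_UNITS: tuple[tuple[str, str], ...] = (
    # ECG / heart-rate variability (14)
    ("mu_HR", "bpm"),
    ("sigma_HR", "bpm"),
    ("Max_HR", "bpm"),
    ("Min_HR", "bpm"),
    ("mu_NN", "ms"),
    ("sigma_NN", "ms"),
    ("Mad_NN", "ms"),
    ("Med_NN", "ms"),
    ("MCV_NN", ""),
    ("RMSSD_NN", "ms"),
    ("pNN20", "%"),
    ("pNN50", "%"),
    ("LF_HRV", "ms^2"),
    ("HF_HRV", "ms^2"),
    # surface EMG, upper trapezius (8)
    ("mu_EMG", "mV"),
    ("sigma_EMG", "mV"),
    ("Max_EMG", "mV"),
    ("Min_EMG", "mV"),
    ("Peaks_EMG", "count"),
    ("RMS_EMG", "mV"),
    ("RMS50P_EMG", "mV"),
    ("RMS90P_EMG", "mV"),
    # electrodermal activity (12)
    ("mu_WristEDA", "uS"),
    ("sigma_WristEDA", "uS"),
    ("Max_WristEDA", "uS"),
    ("Min_WristEDA", "uS"),
    ("mu_ChestEDA", "uS"),
    ("sigma_ChestEDA", "uS"),
    ("Max_ChestEDA", "uS"),
    ("Min_ChestEDA", "uS"),
    ("mu_ChestSCL", "uS"),
    ("sigma_ChestSCL", "uS"),
    ("mu_ChestSCR", "uS"),
    ("sigma_ChestSCR", "uS"),
    # respiration rate (4)
    ("mu_RespRate", "breaths/min"),
    ("sigma_RespRate", "breaths/min"),
    ("Max_RespRate", "breaths/min"),
    ("Min_RespRate", "breaths/min"),
    # wrist temperature (4)
    ("mu_WristTemp", "degC"),
    ("sigma_WristTemp", "degC"),
    ("Max_WristTemp", "degC"),
    ("Min_WristTemp", "degC"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in FEATURE_UNITS)
UNIT_OF: dict[str, str] = dict(FEATURE_UNITS)
N_FEATURES: int = len(FEATURE_NAMES)

#: Tests kept by the "simple" OLAP aggregation level: heart rate,
#: respiration, and body temperature summary statistics only.
SIMPLE_AGGREGATE_FEATURES: tuple[str, ...] = (
    "mu_HR", "sigma_HR", "Max_HR", "Min_HR",
    "mu_RespRate", "sigma_RespRate", "Max_RespRate", "Min_RespRate",
    "mu_WristTemp", "sigma_WristTemp", "Max_WristTemp", "Min_WristTemp",
)

CHANNEL_NAMES: tuple[str, ...] = (
    "ecg", "emg_chest", "eda_chest", "eda_wrist", "temp_wrist", "resp",
)


class StressReportError(Exception):
    """Base class for errors raised by this package."""


class InsufficientBeatsError(StressReportError):
    """Too few heartbeats (or breaths) survive detection/artifact rejection."""


class FeatureExtractionError(StressReportError):
    """A per-window feature extractor failed; the window is identified."""
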