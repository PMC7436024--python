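"""Posture classification of raw thigh-worn accelerometer data.

The embedded-device chain is reproduced in four pure stages:

1. ``denoise`` — zero-phase low-pass filtering of each axis;
2. ``segment`` — fixed, non-overlapping one-second windows aligned to
   whole epoch seconds;
3. ``classify_window`` — dynamic vs static by an activity dispersion
   statistic, static split into standing vs sedentary by the thigh-axis
   orientation against a 0.8 g cut-off;
4. ``aggregate_minutes`` — per-wall-clock-minute second counts.

:class:`PostureClassifier` wraps the chain as a stateless scikit-learn
transformer so it can sit inside a Pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, InputError

SIGNAL_COLUMNS = ["timestamp", "x_g", "y_g", "z_g"]

LABELS = ("sedentary", "standing", "dynamic")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and conventions of the window classifier.

    ``orientation_cutoff_g`` is the published 0.8 g rule: a static
    window whose mean absolute longitudinal acceleration is at or above
    it is standing, below it sedentary.  ``dynamic_threshold_g`` is the
    dispersion cut-off separating ambulation from static postures; the
    embedded statistic is unpublished, so the activity measure used here
    is the largest per-axis mean absolute deviation about the window
    mean — sensitive both to gait oscillation and to orientation changes
    that leave the vector magnitude constant.
    """

    dynamic_threshold_g: float = 0.1
    orientation_cutoff_g: float = 0.8
    longitudinal_axis: str = "z"
    noise_cutoff_hz: float = 5.0
    sample_rate_hz: float = 25.0
    min_samples_per_window: int = 20

    def __post_init__(self):
        if self.dynamic_threshold_g <= 0 or self.orientation_cutoff_g <= 0:
            raise ConfigError("thresholds must be positive")
        if self.longitudinal_axis not in ("x", "y", "z"):
            raise ConfigError("longitudinal_axis must be one of x, y, z")
        if not 0 < self.noise_cutoff_hz < self.sample_rate_hz / 2:
            raise ConfigError("noise_cutoff_hz must lie below the Nyquist rate")


def _validate_signal(signal: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SIGNAL_COLUMNS if c not in signal.columns]
    if missing:
        raise InputError(f"signal frame missing columns {missing}")
    return signal


def denoise(signal: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()) -> pd.DataFrame:
    """Low-pass filter each axis, preserving timestamps and sample count.

    A 4th-order Butterworth filter at ``noise_cutoff_hz`` is applied
    forward and backward (zero phase) to every contiguous run of
    samples; gaps longer than 1.5 sample intervals break a run, since
    filtering across transmission gaps would smear unrelated data
    together.  Runs too short to pad are passed through unchanged.  A
    constant signal is returned unchanged (unit DC gain).
    """
    _validate_signal(signal)
    if signal.empty:
        raise InputError("cannot denoise an empty signal")
    b, a = sps.butter(
        4, config.noise_cutoff_hz, fs=config.sample_rate_hz, btype="low"
    )
    padlen = 3 * max(len(a), len(b))
    out = signal.copy()
    ts = signal["timestamp"].to_numpy()
    dt = np.diff(ts).astype("timedelta64[ns]").astype(np.int64) / 1e9
    gap = 1.5 / config.sample_rate_hz
    run_starts = np.concatenate([[0], np.nonzero(dt > gap)[0] + 1, [len(signal)]])
    for col in ("x_g", "y_g", "z_g"):
        vals = signal[col].to_numpy(dtype=float).copy()
        for s, e in zip(run_starts[:-1], run_starts[1:]):
            if e - s > padlen:
                vals[s:e] = sps.filtfilt(b, a, vals[s:e])
        out[col] = vals
    return out


def segment(
    signal: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Cut a signal into complete one-second windows with features.

    Windows are anchored at whole epoch seconds (fixed, non-overlapping).
    A second is kept only when it holds at least
    ``min_samples_per_window`` samples — sparser seconds count as
    non-wear rather than being classified from fabricated data — so
    partial leading/trailing seconds and coverage gaps yield no windows.

    Returns one row per window: ``start`` (second-aligned timestamp),
    ``n_samples``, ``dispersion_g`` (largest per-axis mean absolute
    deviation about the window mean) and ``long_mean_g`` (mean absolute
    acceleration along the configured longitudinal axis).
    """
    _validate_signal(signal)
    if signal.empty:
        return pd.DataFrame(columns=["start", "n_samples", "dispersion_g", "long_mean_g"])
    df = signal.copy()
    df["start"] = df["timestamp"].dt.floor("s")
    df["_long_abs"] = df[f"{config.longitudinal_axis}_g"].abs()
    g = df.groupby("start", sort=True)
    feats = g.agg(
        n_samples=("_long_abs", "size"),
        long_mean_g=("_long_abs", "mean"),
    )
    # dispersion needs the window mean per axis first, then a second pass
    for ax in ("x_g", "y_g", "z_g"):
        dev = (df[ax] - df.groupby("start")[ax].transform("mean")).abs()
        feats[f"_mad_{ax}"] = dev.groupby(df["start"]).mean()
    feats["dispersion_g"] = feats[[f"_mad_{ax}" for ax in ("x_g", "y_g", "z_g")]].max(axis=1)
    feats = feats[feats["n_samples"] >= config.min_samples_per_window]
    return feats.reset_index()[["start", "n_samples", "dispersion_g", "long_mean_g"]]


def classify_window(
    dispersion_g: float, long_mean_g: float, config: ClassifierConfig = ClassifierConfig()
) -> str:
    """Label one window from its two features.

    Dispersion above ``dynamic_threshold_g`` means ambulation
    (``dynamic``); otherwise the posture is static and the thigh-axis
    orientation decides: mean absolute longitudinal acceleration at or
    above the 0.8 g cut-off means the thigh is vertical (``standing``),
    below it horizontal (``sedentary``).  The boundary is inclusive.
    """
    if dispersion_g > config.dynamic_threshold_g:
        return "dynamic"
    return "standing" if long_mean_g >= config.orientation_cutoff_g else "sedentary"


def classify_windows(
    windows: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Vectorised :func:`classify_window` over a segment() frame."""
    out = windows.copy()
    dynamic = out["dispersion_g"] > config.dynamic_threshold_g
    standing = out["long_mean_g"] >= config.orientation_cutoff_g
    out["label"] = np.where(dynamic, "dynamic", np.where(standing, "standing", "sedentary"))
    return out


def aggregate_minutes(labeled: pd.DataFrame) -> pd.DataFrame:
    """Roll labelled windows up into per-minute second counts.

    One row per wall-clock minute containing at least one classified
    window, with columns ``minute_start, sedentary_s, standing_s,
    dynamic_s, covered_s``; the three counts always partition
    ``covered_s``.
    """
    cols = ["minute_start", "sedentary_s", "standing_s", "dynamic_s", "covered_s"]
    if labeled.empty:
        return pd.DataFrame(columns=cols)
    df = labeled.copy()
    df["minute_start"] = df["start"].dt.floor("min")
    counts = (
        df.pivot_table(
            index="minute_start", columns="label", values="start", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(LABELS), fill_value=0)
        .rename(columns={l: f"{l}_s" for l in LABELS})
        .reset_index()
    )
    counts.columns.name = None
    counts["covered_s"] = counts[[f"{l}_s" for l in LABELS]].sum(axis=1)
    return counts[cols]


class PostureClassifier(TransformerMixin, BaseEstimator):
    """Raw tri-axial signal → per-minute posture counts, as a transformer.

    Stateless: ``fit`` only validates parameters; ``transform`` runs
    denoise → segment → classify → aggregate on a signal frame with
    columns ``timestamp, x_g, y_g, z_g`` and returns the minute-record
    frame.  Parameters mirror :class:`ClassifierConfig`.
    """

    def __init__(
        self,
        dynamic_threshold_g: float = 0.1,
        orientation_cutoff_g: float = 0.8,
        longitudinal_axis: str = "z",
        noise_cutoff_hz: float = 5.0,
        sample_rate_hz: float = 25.0,
        min_samples_per_window: int = 20,
    ):
        self.dynamic_threshold_g = dynamic_threshold_g
        self.orientation_cutoff_g = orientation_cutoff_g
        self.longitudinal_axis = longitudinal_axis
        self.noise_cutoff_hz = noise_cutoff_hz
        self.sample_rate_hz = sample_rate_hz
        self.min_samples_per_window = min_samples_per_window

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            dynamic_threshold_g=self.dynamic_threshold_g,
            orientation_cutoff_g=self.orientation_cutoff_g,
            longitudinal_axis=self.longitudinal_axis,
            noise_cutoff_hz=self.noise_cutoff_hz,
            sample_rate_hz=self.sample_rate_hz,
            min_samples_per_window=self.min_samples_per_window,
        )

    def fit(self, X: pd.DataFrame | None = None, y=None):
        self.config_ = self._config()  # validates
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        config = self._config()
        denoised = denoise(X, config)
        labeled = classify_windows(segment(denoised, config), config)
        return aggregate_minutes(labeled)

    def label_windows(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-window labels (before minute aggregation), for auditing."""
        config = self._config()
        return classify_windows(segment(denoise(X, config), config), config)


def classify_signal(
    signal: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Functional one-shot: signal frame → minute records."""
    labeled = classify_windows(segment(denoise(signal, config), config), config)
    return aggregate_minutes(labeled)
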