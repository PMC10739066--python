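"""Windowed physiological feature extraction.

At a decision time ``t`` the predictor sees the preceding ``tau_p`` seconds
of data, split into 15-s sub-windows.  Eleven base statistics are computed
per sub-window — four electrodermal (tonic level and slope, SCR count and
mean amplitude), three cardiovascular (mean heart rate, SDNN, RMSSD from
BVP-detected beats) and four movement (acceleration-magnitude mean/SD/max
and mean jerk) — and the final feature vector holds the mean and the SD of
each statistic across sub-windows, giving ``2 x 11 = 22`` features.

Windows are half-open ``(t - tau_p, t]``: the sample at exactly
``t - tau_p`` is excluded, the one at ``t`` included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import signal as sps

from .e4_io import SessionRecording

#: ordered base statistics (channel prefix encodes the source signal)
BASE_STATS = (
    "eda_tonic_mean",
    "eda_tonic_slope",
    "eda_scr_count",
    "eda_scr_amp",
    "bvp_hr_mean",
    "bvp_sdnn",
    "bvp_rmssd",
    "acc_mag_mean",
    "acc_mag_sd",
    "acc_mag_max",
    "acc_jerk_mean",
)

SCR_MIN_PROMINENCE_US = 0.01
BVP_BAND_HZ = (0.7, 3.5)
BEAT_REFRACTORY_S = 0.33
IBI_RANGE_S = (0.3, 2.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Window geometry for feature extraction.

    ``tau_p`` (s) is the look-back length, one of {60, 120, 180} in the
    standard grids; it must be a multiple of ``sub_window_s``.
    """

    tau_p: float = 180.0
    sub_window_s: float = 15.0

    def __post_init__(self) -> None:
        n = self.tau_p / self.sub_window_s
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("tau_p must be a positive multiple of sub_window_s")

    @property
    def n_sub(self) -> int:
        return int(round(self.tau_p / self.sub_window_s))


def feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """Deterministic feature order: all sub-window means, then all SDs."""
    return [f"{b}_mean" for b in BASE_STATS] + [f"{b}_sd" for b in BASE_STATS]


def eda_stats(segment: np.ndarray, rate: float = 4.0) -> tuple[float, float, float, float]:
    """(tonic mean uS, tonic slope uS/s, SCR count, mean SCR amplitude uS).

    Tonic is a slow robust baseline (low-percentile filter, ~8-s window);
    the phasic residual is scanned for peaks with prominence >= 0.01 uS.
    A constant segment gives zero slope and zero SCRs.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError("eda segment needs >= 4 samples")
    n = x.size
    if n > 12:
        # robust slow baseline: low-percentile filter over ~8 s windows keeps
        # SCR transients fully in the phasic residual (a linear low-pass
        # absorbs part of each SCR into the tonic estimate)
        size = min(int(8 * rate) | 1, n)
        tonic = ndi.percentile_filter(x, 10, size=size, mode="nearest")
    else:  # too short for a baseline window: tonic = segment mean
        tonic = np.full(n, x.mean())
    t = np.arange(n) / rate
    slope = float(np.polyfit(t, x, 1)[0]) if np.ptp(x) > 0 else 0.0
    phasic = x - tonic
    peaks, props = sps.find_peaks(phasic, prominence=SCR_MIN_PROMINENCE_US)
    amp = float(props["prominences"].mean()) if peaks.size else 0.0
    return float(tonic.mean()), slope, float(peaks.size), amp


def bvp_stats(segment: np.ndarray, rate: float = 64.0) -> tuple[float, float, float]:
    """(mean heart rate bpm, SDNN ms, RMSSD ms) from a BVP segment.

    Beats are local maxima of the 0.7-3.5 Hz band-passed waveform with a
    0.33-s refractory period; inter-beat intervals outside 0.3-2.0 s are
    discarded as detection artifacts.  Fewer than three usable beats yields
    NaNs (imputed downstream and flagged).
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty BVP segment")
    if x.size < int(2 * rate):
        return (np.nan, np.nan, np.nan)
    nyq = rate / 2.0
    b, a = sps.butter(2, [BVP_BAND_HZ[0] / nyq, BVP_BAND_HZ[1] / nyq], "band")
    xf = sps.filtfilt(b, a, x, padlen=min(3 * (max(len(a), len(b)) - 1), x.size - 1))
    sd = xf.std()
    if sd == 0:
        return (np.nan, np.nan, np.nan)
    peaks, _ = sps.find_peaks(
        xf, distance=max(int(BEAT_REFRACTORY_S * rate), 1), prominence=0.5 * sd
    )
    ibi = np.diff(peaks) / rate
    ibi = ibi[(ibi >= IBI_RANGE_S[0]) & (ibi <= IBI_RANGE_S[1])]
    if ibi.size < 2:
        return (np.nan, np.nan, np.nan)
    hr_mean = 60.0 / ibi.mean()
    sdnn = float(np.std(ibi, ddof=1) * 1000.0)
    rmssd = float(np.sqrt(np.mean(np.diff(ibi) ** 2)) * 1000.0)
    return float(hr_mean), sdnn, rmssd


def acc_stats(segment: np.ndarray, rate: float = 32.0) -> tuple[float, float, float, float]:
    """(magnitude mean g, magnitude SD g, magnitude max g, mean jerk g/s).

    Magnitude is the per-sample Euclidean norm; jerk is the mean absolute
    first difference of magnitude times the sampling rate.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValueError("acc segment must be (n >= 2, 3)")
    mag = np.linalg.norm(x, axis=1)
    jerk = float(np.mean(np.abs(np.diff(mag))) * rate)
    return float(mag.mean()), float(mag.std()), float(mag.max()), jerk


def _slice_halfopen(n: int, rate: float, lo: float, hi: float) -> slice:
    """Indices of samples with time in (lo, hi], sample i at time i/rate."""
    i0 = int(np.floor(lo * rate + 1e-9)) + 1
    i1 = int(np.floor(hi * rate + 1e-9)) + 1
    return slice(max(i0, 0), min(i1, n))


def _subwindow_stats(rec: SessionRecording, lo: float, hi: float) -> np.ndarray:
    """The 11 base statistics for the half-open sub-window (lo, hi]."""
    out = np.full(len(BASE_STATS), np.nan)
    eda = rec.eda
    sl = _slice_halfopen(eda.samples.shape[0], eda.rate, lo, hi)
    if sl.stop - sl.start >= 4:
        out[0:4] = eda_stats(eda.samples[sl], eda.rate)
    bvp = rec.bvp
    sl = _slice_halfopen(bvp.samples.shape[0], bvp.rate, lo, hi)
    if sl.stop - sl.start > 0:
        out[4:7] = bvp_stats(bvp.samples[sl], bvp.rate)
    acc = rec.acc
    sl = _slice_halfopen(acc.samples.shape[0], acc.rate, lo, hi)
    if sl.stop - sl.start >= 2:
        out[7:11] = acc_stats(acc.samples[sl], acc.rate)
    return out


@dataclass
class FeatureVector:
    """One extracted window: named values plus decision-point metadata."""

    t: float
    tau_p: float
    participant_id: str
    session_id: str
    names: list[str]
    values: np.ndarray
    imputed: bool  # some base statistic was undefined in >= 1 sub-window


def extract_window(
    rec: SessionRecording,
    t: float,
    cfg: FeatureConfig,
    _cache: dict | None = None,
) -> FeatureVector:
    """Extract the feature vector for the window ``(t - tau_p, t]``.

    Undefined base statistics (e.g. no detectable beats in a sub-window)
    are skipped by the nan-aware aggregation and flag the vector as
    imputed.  ``_cache`` lets batch callers share sub-window statistics.
    """
    if t < cfg.tau_p - 1e-9:
        raise ValueError(f"t={t} precedes the first full window (tau_p={cfg.tau_p})")
    if t > rec.duration_s + 1e-9:
        raise ValueError(f"t={t} beyond session end {rec.duration_s}")
    rows = np.empty((cfg.n_sub, len(BASE_STATS)))
    for k in range(cfg.n_sub):
        lo = t - cfg.tau_p + k * cfg.sub_window_s
        hi = lo + cfg.sub_window_s
        if _cache is not None:
            key = round(lo * 1000)
            if key not in _cache:
                _cache[key] = _subwindow_stats(rec, lo, hi)
            rows[k] = _cache[key]
        else:
            rows[k] = _subwindow_stats(rec, lo, hi)
    has_nan = bool(np.isnan(rows).any())
    with np.errstate(invalid="ignore"):
        means = np.nanmean(rows, axis=0)
        sds = np.nanstd(rows, axis=0)
    values = np.concatenate([means, sds])
    return FeatureVector(
        t=t,
        tau_p=cfg.tau_p,
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        names=feature_names(cfg),
        values=values,
        imputed=has_nan,
    )


def feature_table(
    rec: SessionRecording, times: np.ndarray, cfg: FeatureConfig
) -> pd.DataFrame:
    """Feature vectors for many decision times of one session (wide frame).

    When the decision times sit on the sub-window grid (the 15-s cadence),
    each sub-window statistic is computed once and shared between
    overlapping windows.
    """
    cache: dict = {}
    recs = []
    for t in np.asarray(times, dtype=float):
        fv = extract_window(rec, t, cfg, _cache=cache)
        row = {
            "participant": fv.participant_id,
            "session": fv.session_id,
            "t": fv.t,
            "imputed": fv.imputed,
        }
        row.update(dict(zip(fv.names, fv.values)))
        recs.append(row)
    cols = ["participant", "session", "t", "imputed"] + feature_names(cfg)
    return pd.DataFrame(recs, columns=cols)
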