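"""Acoustic feature sets for tonal calls.

Three complementary parameterizations of a call:

* **Bioacoustic** (20 columns): expert landmarks of the f0 contour (onset,
  offset, mid, mean, max and its time, four piecewise slopes), the spectral
  energy distribution (frequency and time quartiles of the summed energy,
  and the frequency/time of maximal energy), plus duration and HNR.
* **DCT** (7 columns): the first five orthonormal DCT-II amplitudes of the
  uniformly resampled f0 contour — mean level (dct0), global slope (dct1),
  curvature (dct2) and finer shape — plus duration and HNR.
* **MFCC** (192 columns): per-frame mel-frequency cepstra (32 coefficients
  from a 33-filter 500–12000 Hz filterbank, ~23 ms Hamming frames, 50%
  overlap, the zeroth coefficient excluded) with
  delta and delta-delta derivatives, summarized per call by the mean and
  standard deviation of each of the 96 frame-level dimensions.

The union of the three sets deduplicates the shared duration and HNR
columns, giving 217 features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import dct as _scipy_dct

from .corpus import Call, Corpus
from .table import FeatureTable

__all__ = [
    "BIOACOUSTIC_SET",
    "DCT_SET",
    "dct_features",
    "bioacoustic_features",
    "mfcc_features",
    "mfcc_feature_names",
    "f0_template",
    "TemplateSummary",
    "build_feature_table",
    "resample_contour",
    "call_spectrogram",
]

#: default 20-column bioacoustic set. f0.sta / f0.end are computed as well
#: but are near-duplicates of f0.onset / f0.offset on continuous contours
#: and are excluded from the default set; override via ``columns=``.
BIOACOUSTIC_SET = (
    "duration", "hnr",
    "f0.onset", "f0.offset", "f0.mid", "f0.av", "f0.max", "tf0.max",
    "f0.slope.asc", "f0.slope.desc", "f0.slope.1st.half", "f0.slope.2nd.half",
    "q1f", "q2f", "q3f", "f.max", "q1t", "q2t", "q3t", "t.max",
)

DCT_SET = ("dct0", "dct1", "dct2", "dct3", "dct4", "duration", "hnr")


# ---------------------------------------------------------------------------
# contour utilities


def resample_contour(contour: np.ndarray, n: int, duration: float | None = None) -> np.ndarray:
    """Linearly resample f0 values at *n* midpoint times (k+1/2)/n * T.

    Midpoint sampling aligns the samples with the DCT-II basis grid, so a
    half-cycle cosine contour maps onto a single coefficient. Unvoiced gaps
    inside the call are bridged by the interpolation.
    """
    t, f = contour[:, 0], contour[:, 1]
    T = duration if duration is not None else t[-1]
    grid = (np.arange(n) + 0.5) / n * T
    return np.interp(grid, t, f)


# ---------------------------------------------------------------------------
# DCT set


def dct_features(call: Call, n_coefs: int = 5, n_resample: int = 64) -> pd.Series:
    """First *n_coefs* orthonormal DCT-II amplitudes of the f0 contour,
    plus duration and HNR.

    Sign convention: odd-order coefficients are negated so that dct1 is
    positive for a rising contour (and measures direction of change from
    the mean); dct0 is proportional to the contour mean.
    """
    if call.f0_contour is None or len(call.f0_contour) < n_coefs:
        raise ValueError(
            f"{call.call_id}: contour must have at least n_coefs={n_coefs} samples"
        )
    x = resample_contour(call.f0_contour, n_resample, call.duration)
    coefs = _scipy_dct(x, type=2, norm="ortho")[:n_coefs]
    signs = np.where(np.arange(n_coefs) % 2 == 1, -1.0, 1.0)
    coefs = coefs * signs
    names = [f"dct{k}" for k in range(n_coefs)] + ["duration", "hnr"]
    return pd.Series(np.concatenate([coefs, [call.duration, call.hnr]]), index=names)


# ---------------------------------------------------------------------------
# bioacoustic set


@dataclass
class BioacousticVector:
    """Named landmark values plus quality flags for degenerate segments."""

    values: pd.Series
    flags: list[str] = field(default_factory=list)


def call_spectrogram(
    call: Call,
    n_fft: int = 1024,
    overlap: float = 0.5,
    fmin: float = 500.0,
    fmax: float = 12000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band-limited power spectrogram (freqs, times, S) of a call waveform."""
    if call.waveform is None:
        raise ValueError(f"{call.call_id}: no waveform to compute a spectrogram from")
    w = call.waveform
    nper = min(n_fft, len(w.samples))
    freqs, times, S = sps.spectrogram(
        w.samples,
        fs=w.rate,
        window="hamming",
        nperseg=nper,
        noverlap=int(nper * overlap),
        mode="psd",
    )
    band = (freqs >= fmin) & (freqs <= min(fmax, w.rate / 2))
    return freqs[band], times, S[band]


def _weighted_quartiles(axis_vals: np.ndarray, energy: np.ndarray) -> tuple[float, float, float]:
    """Values of *axis_vals* below which 25/50/75% of *energy* lies."""
    cum = np.cumsum(energy)
    total = cum[-1]
    out = []
    for q in (0.25, 0.5, 0.75):
        idx = int(np.searchsorted(cum, q * total))
        out.append(float(axis_vals[min(idx, len(axis_vals) - 1)]))
    return tuple(out)


def bioacoustic_features(
    call: Call,
    spectrogram: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    energy: bool = True,
) -> BioacousticVector:
    """Expert f0-shape and energy-distribution descriptors of a call.

    f0 landmarks are read from the contour: onset/offset are the first/last
    voiced values, start/mid/end are interpolated at t = 0, T/2, T, and the
    four slopes are rise/fall rates over the ascending (onset->max),
    descending (max->offset), first-half and second-half segments. A
    monotone contour has an empty ascending or descending segment; its slope
    is reported as 0 and flagged.

    Energy descriptors (q1f..q3f, f.max, q1t..q3t, t.max) are quartiles and
    maxima of the marginal spectral-energy distributions over frequency and
    time, computed from *spectrogram* (freqs, times, power) or, if absent,
    from the call waveform.
    """
    if call.f0_contour is None or len(call.f0_contour) == 0:
        raise ValueError(f"{call.call_id}: empty f0 contour")
    t, f = call.f0_contour[:, 0], call.f0_contour[:, 1]
    T = call.duration
    flags: list[str] = []

    i_max = int(np.argmax(f))
    f0_max, tf0_max = float(f[i_max]), float(t[i_max])
    f0_onset, f0_offset = float(f[0]), float(f[-1])
    f0_sta = float(np.interp(0.0, t, f))
    f0_mid = float(np.interp(T / 2, t, f))
    f0_end = float(np.interp(T, t, f))
    f0_av = float(np.trapezoid(f, t) / (t[-1] - t[0])) if len(t) > 1 else float(f[0])

    def _slope(df: float, dt: float, name: str) -> float:
        if dt <= 0:
            flags.append(f"{name}: empty segment, slope set to 0")
            return 0.0
        return df / dt

    slope_asc = _slope(f0_max - f0_onset, tf0_max - t[0], "f0.slope.asc")
    slope_desc = _slope(f0_offset - f0_max, t[-1] - tf0_max, "f0.slope.desc")
    half = T / 2
    slope_1st = _slope(f0_mid - f0_sta, half, "f0.slope.1st.half")
    slope_2nd = _slope(f0_end - f0_mid, half, "f0.slope.2nd.half")

    values = {
        "duration": T,
        "hnr": call.hnr,
        "f0.sta": f0_sta,
        "f0.mid": f0_mid,
        "f0.end": f0_end,
        "f0.onset": f0_onset,
        "f0.offset": f0_offset,
        "f0.av": f0_av,
        "f0.max": f0_max,
        "tf0.max": tf0_max,
        "f0.slope.asc": slope_asc,
        "f0.slope.desc": slope_desc,
        "f0.slope.1st.half": slope_1st,
        "f0.slope.2nd.half": slope_2nd,
    }

    if energy:
        if spectrogram is None:
            spectrogram = call_spectrogram(call)
        freqs, times, S = spectrogram
        e_freq = S.sum(axis=1)
        e_time = S.sum(axis=0)
        if e_freq.sum() <= 0:
            raise ValueError(f"{call.call_id}: spectrogram has no energy")
        q1f, q2f, q3f = _weighted_quartiles(freqs, e_freq)
        q1t, q2t, q3t = _weighted_quartiles(times, e_time)
        values.update(
            {
                "q1f": q1f, "q2f": q2f, "q3f": q3f,
                "f.max": float(freqs[int(np.argmax(e_freq))]),
                "q1t": q1t, "q2t": q2t, "q3t": q3t,
                "t.max": float(times[int(np.argmax(e_time))]),
            }
        )
    return BioacousticVector(pd.Series(values), flags)


# ---------------------------------------------------------------------------
# MFCC set


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, rate: float, fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel-spaced filters over [fmin, fmax], shape (n_filters, n_bins)."""
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    edges = _mel_to_hz(mels)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_filters, len(bin_freqs)))
    for i in range(n_filters):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _delta(x: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-based derivative along the frame axis (frames, coefs)."""
    denom = 2 * sum(n * n for n in range(1, width + 1))
    pad = np.pad(x, ((width, width), (0, 0)), mode="edge")
    out = np.zeros_like(x)
    for n in range(1, width + 1):
        out += n * (pad[width + n : width + n + len(x)] - pad[width - n : width - n + len(x)])
    return out / denom


def mfcc_frames(
    samples: np.ndarray,
    rate: float,
    n_coefs: int = 32,
    n_filters: int = 33,
    frame_s: float = 0.023,
    overlap: float = 0.5,
    fmin: float = 500.0,
    fmax: float = 12000.0,
) -> np.ndarray:
    """Per-frame mel cepstra with deltas, shape (n_frames, 3 * n_coefs)."""
    if rate < 2 * fmax:
        raise ValueError(f"sampling rate {rate} Hz cannot cover the {fmax} Hz band")
    n_frame = int(round(frame_s * rate))
    hop = max(1, int(round(n_frame * (1 - overlap))))
    if len(samples) < n_frame + hop:
        raise ValueError(
            f"waveform too short for MFCC: needs >= {(n_frame + hop) / rate:.3f} s (two frames)"
        )
    window = np.hamming(n_frame)
    n_frames = 1 + (len(samples) - n_frame) // hop
    idx = np.arange(n_frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = samples[idx] * window
    spec = np.abs(np.fft.rfft(frames, n=n_frame, axis=1)) ** 2
    fb = _mel_filterbank(n_filters, n_frame, rate, fmin, fmax)
    logmel = np.log(np.maximum(spec @ fb.T, 1e-12))
    cep = _scipy_dct(logmel, type=2, norm="ortho", axis=1)[:, 1 : n_coefs + 1]
    d = _delta(cep)
    dd = _delta(d)
    return np.hstack([cep, d, dd])


def mfcc_feature_names(n_coefs: int = 32) -> list[str]:
    blocks = (
        [f"mfcc{k:02d}" for k in range(1, n_coefs + 1)]
        + [f"d{k:02d}" for k in range(1, n_coefs + 1)]
        + [f"dd{k:02d}" for k in range(1, n_coefs + 1)]
    )
    return [f"{b}.mean" for b in blocks] + [f"{b}.sd" for b in blocks]


def mfcc_features(call: Call, **kwargs) -> pd.Series:
    """Call-level MFCC summary: per-coefficient mean and sd over frames.

    32 cepstral coefficients + 32 deltas + 32 delta-deltas, each summarized
    by its mean and standard deviation across frames -> 192 values.
    """
    if call.waveform is None:
        raise ValueError(f"{call.call_id}: no waveform for MFCC extraction")
    fr = mfcc_frames(call.waveform.samples, call.waveform.rate, **kwargs)
    means = fr.mean(axis=0)
    sds = fr.std(axis=0, ddof=0)
    n_coefs = fr.shape[1] // 3
    return pd.Series(np.concatenate([means, sds]), index=mfcc_feature_names(n_coefs))


# ---------------------------------------------------------------------------
# f0 templates


@dataclass
class TemplateSummary:
    """Time-normalized mean f0 trajectory of one call type with percentile bands."""

    call_type: str
    n_calls: int
    mean_duration: float
    sd_duration: float
    mean_hnr: float
    sd_hnr: float
    grid: np.ndarray          # times on [0, mean_duration]
    mean_f0: np.ndarray
    bands: dict               # {50: (lo, hi), 80: (lo, hi)} pointwise arrays


def f0_template(
    calls: list[Call],
    grid_size: int = 100,
    bands: tuple[int, int] = (50, 80),
) -> TemplateSummary:
    """Average f0 trajectory of a call type.

    Every contour is linearly time-rescaled to the type's mean duration and
    resampled on a common grid; the template is the pointwise mean with
    central percentile bands (e.g. the 50% band spans the 25th–75th
    pointwise percentiles).
    """
    if not calls:
        raise ValueError("f0_template requires at least one call")
    types = {c.call_type for c in calls}
    if len(types) > 1:
        raise ValueError(f"calls must share a type, got {sorted(types)}")
    durs = np.array([c.duration for c in calls])
    hnrs = np.array([c.hnr for c in calls])
    mean_dur = float(durs.mean())
    grid = np.linspace(0.0, mean_dur, grid_size)
    curves = np.empty((len(calls), grid_size))
    for i, c in enumerate(calls):
        if c.f0_contour is None or len(c.f0_contour) == 0:
            raise ValueError(f"{c.call_id}: missing contour")
        t, f = c.f0_contour[:, 0], c.f0_contour[:, 1]
        scale = mean_dur / c.duration
        curves[i] = np.interp(grid, t * scale, f)
    band_arrays = {}
    for pct in bands:
        lo_q, hi_q = 50 - pct / 2, 50 + pct / 2
        band_arrays[pct] = (
            np.percentile(curves, lo_q, axis=0),
            np.percentile(curves, hi_q, axis=0),
        )
    return TemplateSummary(
        call_type=types.pop(),
        n_calls=len(calls),
        mean_duration=mean_dur,
        sd_duration=float(durs.std(ddof=1)) if len(calls) > 1 else 0.0,
        mean_hnr=float(hnrs.mean()),
        sd_hnr=float(hnrs.std(ddof=1)) if len(calls) > 1 else 0.0,
        grid=grid,
        mean_f0=curves.mean(axis=0),
        bands=band_arrays,
    )


# ---------------------------------------------------------------------------
# table assembly


def build_feature_table(
    corpus: Corpus,
    feature_set: str = "union",
    bioacoustic_columns: tuple[str, ...] = BIOACOUSTIC_SET,
) -> FeatureTable:
    """Extract one feature set (or their deduplicated union) for every call."""
    if feature_set not in ("bioacoustic", "dct", "mfcc", "union"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    rows = []
    for call in corpus:
        parts = []
        if feature_set in ("bioacoustic", "union"):
            vec = bioacoustic_features(call)
            parts.append(vec.values[list(bioacoustic_columns)])
        if feature_set in ("dct", "union"):
            d = dct_features(call)
            if feature_set == "union":
                d = d.drop(["duration", "hnr"])
            parts.append(d)
        if feature_set in ("mfcc", "union"):
            parts.append(mfcc_features(call))
        row = pd.concat(parts)
        row["individual_id"] = call.individual_id
        row["call_type"] = call.call_type
        row["sequence_id"] = call.sequence_id
        row.name = call.call_id
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "call_id"
    label_cols = ["individual_id", "call_type", "sequence_id"]
    feat_cols = [c for c in df.columns if c not in label_cols]
    df[feat_cols] = df[feat_cols].astype(float)
    return FeatureTable(df, feature_set)
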