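"""Minute-level features, quality flags and the smoothed reference series.

Raw streams are aggregated to one sample per minute (mean over half-open
windows ``[60(n-1), 60n)`` seconds, 1-based minute index ``n``).  Quality
criteria flag minutes that contain null, negative or strongly oscillating
samples, minutes with too few samples, and minutes spent out of bed; a
session enters model training only when at least 80 % of both the strip and
the wrist reference minutes are valid.  For every valid minute the five
strip values are sorted descending and the top three (the sensors most
likely touching the body) become the stage-one feature vector.  The wrist
reference is robust-LOWESS smoothed at full rate and then reduced to one
sample per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .simulate import RawStream, SessionRecording, STRIP_CHANNELS

__all__ = [
    "FLAG_VALID", "FLAG_MISSING", "FLAG_NULL", "FLAG_NEGATIVE",
    "FLAG_OSCILLATION", "FLAG_BED_ABSENT",
    "MinuteSeries", "QualityMask", "SortedTriple", "ReferenceSeries",
    "GateResult", "aggregate_minute", "flag_invalid_minutes",
    "mask_bed_absence", "pooled_strip_mask", "session_quality_gate",
    "select_top3", "select_top3_series", "smooth_reference",
    "lowess_smooth_series", "build_feature_table",
    "DEFAULT_OSCILLATION_THRESHOLD", "DEFAULT_QUALITY_THRESHOLD",
]

FLAG_VALID = "valid"
FLAG_MISSING = "missing"
FLAG_NULL = "null_invalid"
FLAG_NEGATIVE = "negative_invalid"
FLAG_OSCILLATION = "oscillation_invalid"
FLAG_BED_ABSENT = "bed_absent"

#: intra-minute range (max - min, degC) above which a minute is flagged as
#: an electronic oscillation artifact
DEFAULT_OSCILLATION_THRESHOLD = 2.0
#: minimum fraction of valid minutes (strip AND reference) for a session to
#: enter training; "at least 80 %" is inclusive
DEFAULT_QUALITY_THRESHOLD = 0.80


@dataclass
class MinuteSeries:
    """Per-minute mean values for one channel (NaN where no aggregate)."""

    minute_index: np.ndarray   # 1-based, contiguous
    values: np.ndarray         # degC
    sample_counts: np.ndarray  # raw samples per minute
    nominal_rate: float        # samples/s of the source stream
    channel: str = ""

    def __len__(self) -> int:
        return int(self.minute_index.size)


@dataclass
class QualityMask:
    """One flag per minute plus the derived good fraction."""

    minute_index: np.ndarray
    flags: np.ndarray  # of str, one of the FLAG_* constants

    @property
    def good_fraction(self) -> float:
        if self.flags.size == 0:
            return 0.0
        return float(np.mean(self.flags == FLAG_VALID))

    @property
    def valid(self) -> np.ndarray:
        return self.flags == FLAG_VALID

    def copy(self) -> "QualityMask":
        return QualityMask(self.minute_index.copy(), self.flags.copy())


@dataclass(frozen=True)
class SortedTriple:
    """Top three strip values at one minute, descending, with sources."""

    minute_index: int
    values: tuple   # (V1, V2, V3), V1 >= V2 >= V3
    sources: tuple  # sensor indices in 1..5, distinct


@dataclass
class ReferenceSeries:
    """Smoothed, per-minute ground-truth distal skin temperature S(n)."""

    minute_index: np.ndarray
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.minute_index, name="S")


@dataclass(frozen=True)
class GateResult:
    included: bool
    tss_good_fraction: float
    ref_good_fraction: float
    reason: str = ""


# ---------------------------------------------------------------------------
# aggregation and flags
# ---------------------------------------------------------------------------

def aggregate_minute(stream: RawStream, n_minutes: Optional[int] = None) -> MinuteSeries:
    """Aggregate a raw stream to one mean value per minute.

    Minute ``n`` (1-based) covers seconds ``[60(n-1), 60n)``.  Minutes with
    fewer than 50 % of the nominal sample count are reported as NaN and will
    be flagged ``missing`` downstream.  NaN (null) samples do not contribute
    to the mean but do count toward sample presence — their invalidity is
    handled by the quality flags, not by aggregation.
    """
    if n_minutes is None:
        n_minutes = 0 if stream.timestamps.size == 0 else int(
            np.ceil(stream.timestamps.max() / 60.0))
    idx = np.arange(1, n_minutes + 1)
    if stream.timestamps.size == 0 or n_minutes == 0:
        return MinuteSeries(idx, np.full(n_minutes, np.nan),
                            np.zeros(n_minutes, dtype=int),
                            stream.nominal_rate, stream.channel)
    minute = np.floor(stream.timestamps / 60.0).astype(int)
    keep = (minute >= 0) & (minute < n_minutes)
    minute = minute[keep]
    vals = stream.values[keep]

    counts = np.bincount(minute, minlength=n_minutes)
    finite = np.isfinite(vals)
    sums = np.bincount(minute[finite], weights=vals[finite], minlength=n_minutes)
    n_finite = np.bincount(minute[finite], minlength=n_minutes)
    with np.errstate(invalid="ignore"):
        means = np.where(n_finite > 0, sums / np.maximum(n_finite, 1), np.nan)

    min_samples = 0.5 * stream.nominal_rate * 60.0
    means = np.where(counts >= min_samples, means, np.nan)
    return MinuteSeries(idx, means, counts, stream.nominal_rate, stream.channel)


def flag_invalid_minutes(series: MinuteSeries, raw: RawStream,
                         oscillation_threshold: float = DEFAULT_OSCILLATION_THRESHOLD,
                         ) -> QualityMask:
    """Flag each minute: null > negative > oscillation > missing > valid.

    A minute is ``null_invalid`` if any raw sample in it is null (NaN),
    ``negative_invalid`` if any sample is < 0 degC, ``oscillation_invalid``
    if the intra-minute range (max - min) exceeds ``oscillation_threshold``.
    """
    n_minutes = len(series)
    flags = np.full(n_minutes, FLAG_VALID, dtype=object)

    minute = np.floor(raw.timestamps / 60.0).astype(int)
    keep = (minute >= 0) & (minute < n_minutes)
    minute = minute[keep]
    vals = raw.values[keep]

    isnan = np.isnan(vals)
    has_null = np.bincount(minute[isnan], minlength=n_minutes) > 0
    has_neg = np.bincount(minute[vals < 0], minlength=n_minutes) > 0

    finite = np.isfinite(vals)
    rng = np.full(n_minutes, 0.0)
    if finite.any():
        mmax = np.full(n_minutes, -np.inf)
        mmin = np.full(n_minutes, np.inf)
        np.maximum.at(mmax, minute[finite], vals[finite])
        np.minimum.at(mmin, minute[finite], vals[finite])
        present = np.isfinite(mmax) & np.isfinite(mmin)
        rng[present] = (mmax - mmin)[present]

    missing = ~np.isfinite(series.values)
    flags[missing] = FLAG_MISSING
    flags[rng > oscillation_threshold] = FLAG_OSCILLATION
    flags[has_neg] = FLAG_NEGATIVE
    flags[has_null] = FLAG_NULL
    return QualityMask(series.minute_index.copy(), flags)


def mask_bed_absence(mask: QualityMask, presence_intervals: Sequence) -> QualityMask:
    """Flag minutes with < 50 % overlap with the presence intervals as
    ``bed_absent`` (data out of bed are discarded regardless of quality)."""
    out = mask.copy()
    for i, n in enumerate(out.minute_index):
        lo, hi = 60.0 * (n - 1), 60.0 * n
        overlap = 0.0
        for a, b in presence_intervals:
            overlap += max(0.0, min(hi, b) - max(lo, a))
        if overlap < 0.5 * (hi - lo):
            out.flags[i] = FLAG_BED_ABSENT
    return out


def pooled_strip_mask(masks: Sequence[QualityMask]) -> QualityMask:
    """Combine the five per-sensor masks: a minute is valid only when all
    five sensors are valid; otherwise the first non-valid flag (in channel
    order) is propagated."""
    if not masks:
        raise ValueError("no masks given")
    idx = masks[0].minute_index
    flags = np.full(idx.size, FLAG_VALID, dtype=object)
    for m in masks:
        if not np.array_equal(m.minute_index, idx):
            raise ValueError("masks cover different minute spans")
        take = (flags == FLAG_VALID) & (m.flags != FLAG_VALID)
        flags[take] = m.flags[take]
    return QualityMask(idx.copy(), flags)


def session_quality_gate(tss_mask: QualityMask, ref_mask: QualityMask,
                         threshold: float = DEFAULT_QUALITY_THRESHOLD) -> GateResult:
    """Session inclusion rule: both the pooled strip and the reference must
    have a good fraction >= ``threshold`` (inclusive boundary)."""
    if len(tss_mask.flags) == 0 or len(ref_mask.flags) == 0:
        return GateResult(False, 0.0, 0.0, reason="zero-length session")
    tf, rf = tss_mask.good_fraction, ref_mask.good_fraction
    if tf < threshold:
        return GateResult(False, tf, rf, reason="strip quality below threshold")
    if rf < threshold:
        return GateResult(False, tf, rf, reason="reference quality below threshold")
    return GateResult(True, tf, rf)


# ---------------------------------------------------------------------------
# top-3 selection
# ---------------------------------------------------------------------------

def select_top3(values: Sequence[float], minute_index: int = 0) -> SortedTriple:
    """Sort the five strip values descending and keep the top three.

    Ties break toward the smaller sensor index (stable sort).  Any
    non-finite value disqualifies the minute.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (5,):
        raise ValueError("select_top3 expects exactly five values")
    if not np.all(np.isfinite(v)):
        raise ValueError("all five strip values must be valid for top-3 selection")
    order = np.argsort(-v, kind="stable")[:3]
    return SortedTriple(minute_index=int(minute_index),
                        values=tuple(float(x) for x in v[order]),
                        sources=tuple(int(i) + 1 for i in order))


def select_top3_series(strip_matrix: np.ndarray):
    """Vectorised top-3 over an (n_minutes, 5) matrix.

    Returns ``(V, idx)`` with ``V`` of shape (n, 3) descending per row and
    ``idx`` the 1-based source sensors.  Rows with any non-finite entry
    yield NaN values.
    """
    m = np.asarray(strip_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 5:
        raise ValueError("expected an (n_minutes, 5) matrix")
    order = np.argsort(-m, axis=1, kind="stable")[:, :3]
    V = np.take_along_axis(m, order, axis=1)
    bad = ~np.all(np.isfinite(m), axis=1)
    V[bad] = np.nan
    return V, order + 1


# ---------------------------------------------------------------------------
# LOWESS reference smoothing
# ---------------------------------------------------------------------------

def lowess_smooth_series(t: np.ndarray, v: np.ndarray, frac: float,
                         it: int = 3, delta_seconds: float = 30.0) -> np.ndarray:
    """Robust LOWESS of ``v`` against ``t`` (seconds), returning the smooth
    evaluated at ``t``.  ``delta_seconds`` linearly interpolates between
    nearby fit points, which keeps full-rate smoothing affordable."""
    return _sm_lowess(v, t, frac=frac, it=it, delta=delta_seconds,
                      return_sorted=False)


def smooth_reference(wrist: RawStream, lowess_frac: Optional[float] = None,
                     lowess_iter: int = 3,
                     n_minutes: Optional[int] = None) -> ReferenceSeries:
    """Robust-LOWESS smooth the full-rate wrist stream, then take per-minute
    means of the smoothed values (anti-aliasing subsampling to 1/min).

    ``lowess_frac`` defaults to 0.05 of the session, floored so the local
    window always spans at least 10 minutes of samples.
    """
    finite = np.isfinite(wrist.values) & (wrist.values > 0)
    t = wrist.timestamps[finite]
    v = wrist.values[finite]
    if t.size == 0:
        return ReferenceSeries(np.array([], dtype=int), np.array([]))
    span_minutes = (t.max() - t.min()) / 60.0
    if span_minutes < 10:
        raise ValueError("wrist stream must cover at least 10 minutes")
    if lowess_frac is None:
        lowess_frac = max(0.05, min(1.0, 10.0 / span_minutes))
    smooth = lowess_smooth_series(t, v, frac=lowess_frac, it=lowess_iter)
    smoothed = RawStream(wrist.channel, t, smooth, wrist.nominal_rate,
                         wrist.resolution)
    agg = aggregate_minute(smoothed, n_minutes=n_minutes)
    return ReferenceSeries(agg.minute_index, agg.values)


# ---------------------------------------------------------------------------
# session-level feature assembly
# ---------------------------------------------------------------------------

def build_feature_table(rec: SessionRecording,
                        oscillation_threshold: float = DEFAULT_OSCILLATION_THRESHOLD,
                        quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
                        with_reference: Optional[bool] = None):
    """Run the full preprocessing chain for one session.

    Returns ``(features, gate)``: a DataFrame with columns
    ``n, T1..T5, V1, V2, V3, valid`` (plus ``S`` when a wrist reference is
    present) and the session's :class:`GateResult`.  ``valid`` marks minutes
    where all five strip sensors pass quality and the sleeper is in bed;
    when a reference is used, rows also require a finite ``S``.
    """
    n_minutes = int(np.floor(rec.duration_minutes))
    if with_reference is None:
        with_reference = "wrist" in rec.streams

    strip_agg = []
    strip_masks = []
    for ch in STRIP_CHANNELS:
        agg = aggregate_minute(rec.streams[ch], n_minutes=n_minutes)
        mask = flag_invalid_minutes(agg, rec.streams[ch], oscillation_threshold)
        mask = mask_bed_absence(mask, rec.presence_intervals)
        strip_agg.append(agg)
        strip_masks.append(mask)
    tss_mask = pooled_strip_mask(strip_masks)

    strip_matrix = np.column_stack([a.values for a in strip_agg])
    strip_matrix = np.where(tss_mask.valid[:, None], strip_matrix, np.nan)
    V, _src = select_top3_series(strip_matrix)

    df = pd.DataFrame({"n": np.arange(1, n_minutes + 1)})
    for i, a in enumerate(strip_agg):
        df[f"T{i + 1}"] = a.values
    df["V1"], df["V2"], df["V3"] = V[:, 0], V[:, 1], V[:, 2]
    valid = tss_mask.valid & np.all(np.isfinite(V), axis=1)

    if with_reference:
        wrist = rec.streams["wrist"]
        wrist_agg = aggregate_minute(wrist, n_minutes=n_minutes)
        ref_mask = flag_invalid_minutes(wrist_agg, wrist, oscillation_threshold)
        ref_mask = mask_bed_absence(ref_mask, rec.presence_intervals)
        ref = smooth_reference(wrist, n_minutes=n_minutes)
        s = np.full(n_minutes, np.nan)
        s[ref.minute_index - 1] = ref.values
        s = np.where(ref_mask.valid, s, np.nan)
        df["S"] = s
        valid = valid & np.isfinite(s)
        gate = session_quality_gate(tss_mask, ref_mask, quality_threshold)
    else:
        gate = GateResult(True, tss_mask.good_fraction, np.nan,
                          reason="no reference channel")

    df["valid"] = valid
    return df, gate
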