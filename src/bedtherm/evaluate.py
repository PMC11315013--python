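"""Accuracy machinery for the DST estimator.

Agreement between the reference series S(n) and the final estimate Y(n) is
summarised per sleep session with Bland–Altman statistics — the bias
(mean of S − Y), the standard deviation of the differences SD_d (n−1
denominator), and the 95 % limits of agreement bias ± 1.96·SD_d — together
with the coefficient of determination R².  Sessions aggregate to folds and
folds to grand means, all unweighted.  Cross-validation is subject-blocked:
a participant's nights are an indivisible block, so no subject contributes
to both training and validation.  The lights-off verification builds
change curves (temperature minus its value at lights-off, minutes 0–60),
grand-averages them across lab sessions and correlates the estimated-DST
curve with the measured foot curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import preprocess
from .estimator import (DEFAULT_CONFIG, HyperparamConfig, PipelineModel,
                        predict_session, train_sequential)
from .preprocess import aggregate_minute, build_feature_table, lowess_smooth_series
from .simulate import StudyFixture

__all__ = [
    "AgreementUndefinedError", "ConstantReferenceError", "AgreementStats",
    "FoldResult", "CVResult", "StudyFeatures", "VerificationResult",
    "bland_altman", "r_squared", "smooth_estimate", "session_agreement",
    "make_subject_folds", "preprocess_study", "run_cv", "learning_curve",
    "change_curve", "grand_average_and_correlate", "verify_lights_off",
]

Z_95 = 1.96  # normal quantile defining the 95 % limits of agreement


class AgreementUndefinedError(ValueError):
    """Fewer than two paired minutes: agreement statistics are undefined."""


class ConstantReferenceError(ValueError):
    """The reference series is constant: R² is undefined."""


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary (and optionally R²) for one sleep session."""

    bias: float
    sd_d: float
    lower_loa: float
    upper_loa: float
    m: int
    r2: Optional[float] = None


@dataclass
class FoldResult:
    fold_id: int
    val_subjects: tuple
    session_stats: list  # of (session_id, AgreementStats)
    train_subjects: tuple = ()
    bias: float = np.nan
    sd_d: float = np.nan
    lower_loa: float = np.nan
    upper_loa: float = np.nan
    r2: float = np.nan

    def __post_init__(self):
        if self.session_stats:
            a = [s for _, s in self.session_stats]
            self.bias = float(np.mean([s.bias for s in a]))
            self.sd_d = float(np.mean([s.sd_d for s in a]))
            self.lower_loa = float(np.mean([s.lower_loa for s in a]))
            self.upper_loa = float(np.mean([s.upper_loa for s in a]))
            self.r2 = float(np.mean([s.r2 for s in a]))


@dataclass
class CVResult:
    folds: list
    grand_means: dict
    excluded_sessions: list = field(default_factory=list)

    def fold_table(self) -> pd.DataFrame:
        rows = [{"fold": f.fold_id, "bias": f.bias,
                 "lower_loa": f.lower_loa, "upper_loa": f.upper_loa,
                 "r2": f.r2} for f in self.folds]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def _paired(s, y):
    if isinstance(s, pd.Series) and isinstance(y, pd.Series):
        common = s.index.intersection(y.index)
        s = s.loc[common].to_numpy(dtype=float)
        y = y.loc[common].to_numpy(dtype=float)
    else:
        s = np.asarray(s, dtype=float)
        y = np.asarray(y, dtype=float)
        if s.shape != y.shape:
            raise ValueError("unaligned inputs must have equal length")
    ok = np.isfinite(s) & np.isfinite(y)
    return s[ok], y[ok]


def bland_altman(s, y) -> AgreementStats:
    """Bland–Altman agreement between reference ``s`` and estimate ``y``.

    Series inputs are aligned on their minute index; array inputs pairwise.
    Over the m paired minutes: bias = mean(s − y), SD_d = sample standard
    deviation of the differences (m − 1 denominator), limits of agreement
    bias ∓ 1.96·SD_d.
    """
    s, y = _paired(s, y)
    m = s.size
    if m < 2:
        raise AgreementUndefinedError(
            f"need at least 2 paired minutes, got {m}")
    d = s - y
    bias = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, sd_d=sd_d,
                          lower_loa=bias - Z_95 * sd_d,
                          upper_loa=bias + Z_95 * sd_d, m=int(m))


def r_squared(s, y) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot of ``y`` against the
    reference ``s`` (SS_tot about mean(s))."""
    s, y = _paired(s, y)
    if s.size < 2:
        raise AgreementUndefinedError(
            f"need at least 2 paired minutes, got {s.size}")
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantReferenceError("reference series is constant")
    ss_res = float(np.sum((s - y) ** 2))
    return 1.0 - ss_res / ss_tot


def smooth_estimate(y: pd.Series, frac: Optional[float] = None,
                    it: int = 3) -> pd.Series:
    """Robust-LOWESS smooth a per-minute estimate series before comparison
    with the reference (same smoother family as the reference itself)."""
    if len(y) < 3:
        return y.copy()
    t = y.index.to_numpy(dtype=float) * 60.0
    span_minutes = (t.max() - t.min()) / 60.0
    if frac is None:
        frac = max(0.05, min(1.0, 10.0 / max(span_minutes, 1.0)))
    sm = lowess_smooth_series(t, y.to_numpy(dtype=float), frac=frac, it=it,
                              delta_seconds=60.0)
    return pd.Series(sm, index=y.index, name=y.name)


def session_agreement(s: pd.Series, y: pd.Series,
                      smooth: bool = True) -> AgreementStats:
    """Full per-session accuracy: LOWESS-smooth the estimate (optional),
    then Bland–Altman statistics plus R² on the paired minutes."""
    ysm = smooth_estimate(y) if smooth else y
    ba = bland_altman(s, ysm)
    r2 = r_squared(s, ysm)
    return AgreementStats(bias=ba.bias, sd_d=ba.sd_d, lower_loa=ba.lower_loa,
                          upper_loa=ba.upper_loa, m=ba.m, r2=r2)


# ---------------------------------------------------------------------------
# subject-blocked cross-validation
# ---------------------------------------------------------------------------

def make_subject_folds(subject_ids: Sequence[str], k: int = 5,
                       seed: int = 0) -> list:
    """Partition subjects into k mutually exclusive, collectively exhaustive
    folds with sizes differing by at most one; deterministic under seed."""
    subjects = list(subject_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(subjects):
        raise ValueError(f"cannot make {k} folds from {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return [sorted(subjects[i] for i in chunk)
            for chunk in np.array_split(order, k)]


@dataclass
class StudyFeatures:
    """Preprocessed, quality-gated feature tables grouped by subject."""

    by_subject: dict  # subject_id -> list of (session_id, DataFrame)
    excluded: list    # of (session_id, reason)

    @property
    def subjects(self) -> list:
        return sorted(self.by_subject)

    def tables_for(self, subjects) -> list:
        return [df for s in subjects for _, df in self.by_subject.get(s, [])]


def preprocess_study(fixture: StudyFixture, setting: str = "home",
                     oscillation_threshold: float = preprocess.DEFAULT_OSCILLATION_THRESHOLD,
                     quality_threshold: float = preprocess.DEFAULT_QUALITY_THRESHOLD,
                     ) -> StudyFeatures:
    """Build feature tables for every session of one setting, applying the
    80 % session quality gate (sessions failing it are excluded)."""
    by_subject: dict = {}
    excluded = []
    for rec in fixture.sessions_for(setting):
        df, gate = build_feature_table(rec, oscillation_threshold,
                                       quality_threshold)
        if not gate.included:
            excluded.append((rec.session_id, gate.reason))
            continue
        by_subject.setdefault(rec.subject_id, []).append((rec.session_id, df))
    return StudyFeatures(by_subject=by_subject, excluded=excluded)


def _resolve_features(fixture_or_features, setting="home") -> StudyFeatures:
    if isinstance(fixture_or_features, StudyFeatures):
        return fixture_or_features
    return preprocess_study(fixture_or_features, setting=setting)


def _fold_model_seed(seed: int, fold_id: int) -> int:
    return (int(seed) * 1009 + fold_id) % (2**31 - 1)


def run_cv(fixture_or_features: Union[StudyFixture, StudyFeatures],
           config: HyperparamConfig = DEFAULT_CONFIG, k: int = 5,
           seed: int = 0) -> CVResult:
    """Subject-blocked k-fold cross-validation of the two-stage estimator.

    Per fold: train sequentially on the other k−1 subject subsets, then
    score every session of the held-out subjects (smoothed estimate vs
    reference: Bland–Altman + R²), average sessions to fold level, and
    average folds (unweighted) to grand means.
    """
    feats = _resolve_features(fixture_or_features)
    subjects = feats.subjects
    folds = make_subject_folds(subjects, k=k, seed=seed)

    fold_results = []
    for fold_id, val_subjects in enumerate(folds, start=1):
        train_subjects = [s for s in subjects if s not in val_subjects]
        assert not set(train_subjects) & set(val_subjects)
        model = train_sequential(feats.tables_for(train_subjects), config,
                                 seed=_fold_model_seed(seed, fold_id),
                                 train_subjects=train_subjects)
        session_stats = []
        for vs in val_subjects:
            for session_id, df in feats.by_subject.get(vs, []):
                y = predict_session(model, df)
                if y.empty:
                    continue
                s = df.set_index("n")["S"]
                try:
                    session_stats.append((session_id, session_agreement(s, y)))
                except (AgreementUndefinedError, ConstantReferenceError):
                    continue
        if not session_stats:
            warnings.warn(f"fold {fold_id}: no surviving validation session; "
                          "excluded from grand means")
        fold_results.append(FoldResult(fold_id=fold_id,
                                       val_subjects=tuple(val_subjects),
                                       session_stats=session_stats,
                                       train_subjects=tuple(train_subjects)))

    scored = [f for f in fold_results if f.session_stats]
    grand = {key: float(np.mean([getattr(f, key) for f in scored]))
             for key in ("bias", "sd_d", "lower_loa", "upper_loa", "r2")}
    return CVResult(folds=fold_results, grand_means=grand,
                    excluded_sessions=feats.excluded)


def learning_curve(fixture_or_features, fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
                   config: HyperparamConfig = DEFAULT_CONFIG, k: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Mean train/validation R² across folds versus the fraction of
    training subjects used.

    Subsampling is at subject granularity; at fraction 1.0 the folds, model
    seeds and therefore the validation means coincide with :func:`run_cv`
    under the same seed.
    """
    feats = _resolve_features(fixture_or_features)
    subjects = feats.subjects
    folds = make_subject_folds(subjects, k=k, seed=seed)
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        train_scores, val_scores = [], []
        for fold_id, val_subjects in enumerate(folds, start=1):
            pool = [s for s in subjects if s not in val_subjects]
            n_take = int(round(frac * len(pool)))
            if n_take < 1:
                warnings.warn(f"fraction {frac} yields no training subject; skipped")
                break
            sub_rng = np.random.default_rng(
                (_fold_model_seed(seed, fold_id) + int(frac * 1e6)) % (2**31 - 1))
            if n_take == len(pool):
                take = pool
            else:
                take = sorted(sub_rng.permutation(pool)[:n_take].tolist())
            model = train_sequential(feats.tables_for(take), config,
                                     seed=_fold_model_seed(seed, fold_id),
                                     train_subjects=take)

            def _mean_r2(subject_list):
                scores = []
                for s_id in subject_list:
                    for _, df in feats.by_subject.get(s_id, []):
                        y = predict_session(model, df)
                        if y.empty:
                            continue
                        try:
                            scores.append(
                                session_agreement(df.set_index("n")["S"], y).r2)
                        except (AgreementUndefinedError, ConstantReferenceError):
                            continue
                return float(np.mean(scores)) if scores else np.nan
            train_scores.append(_mean_r2(take))
            val_scores.append(_mean_r2(val_subjects))
        else:
            rows.append({"fraction": frac,
                         "train_r2": float(np.nanmean(train_scores)),
                         "val_r2": float(np.nanmean(val_scores))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lights-off change curves
# ---------------------------------------------------------------------------

def change_curve(series: pd.Series, lights_off: Optional[float],
                 horizon: int = 60) -> np.ndarray:
    """Temperature change relative to lights-off.

    ``series`` is per-minute (1-based index), ``lights_off`` in seconds from
    session start.  Returns ``horizon + 1`` deltas for minutes 0..horizon
    after lights-off; the anchor delta is exactly 0 and minutes missing from
    the series propagate as NaN.
    """
    if lights_off is None:
        raise ValueError("session has no lights-off event")
    m0 = int(np.floor(lights_off / 60.0)) + 1
    if m0 not in series.index or not np.isfinite(series.loc[m0]):
        raise ValueError("series does not cover the lights-off minute")
    v0 = float(series.loc[m0])
    out = np.full(horizon + 1, np.nan)
    for j in range(horizon + 1):
        m = m0 + j
        if m in series.index:
            out[j] = float(series.loc[m]) - v0
    out[0] = 0.0
    return out


def grand_average_and_correlate(curves_a: Sequence[np.ndarray],
                                curves_b: Sequence[np.ndarray]):
    """Pointwise unweighted mean of each curve group (NaN-ignoring) and the
    Pearson correlation (with two-sided p) between the two mean curves."""
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("need at least 2 curves per group")
    mean_a = np.nanmean(np.vstack(curves_a), axis=0)
    mean_b = np.nanmean(np.vstack(curves_b), axis=0)
    ok = np.isfinite(mean_a) & np.isfinite(mean_b)
    if ok.sum() < 2:
        raise ValueError("no overlapping defined minutes between the groups")
    r, p = _scipy_stats.pearsonr(mean_a[ok], mean_b[ok])
    return mean_a, mean_b, float(r), float(p)


@dataclass
class VerificationResult:
    mean_estimated_curve: np.ndarray
    mean_foot_curve: np.ndarray
    pearson_r: float
    p_value: float
    n_sessions: int


def verify_lights_off(fixture: StudyFixture, model: PipelineModel,
                      horizon: int = 60, smooth: bool = True) -> VerificationResult:
    """Lights-off verification on the lab sessions.

    For every lab session, estimate the DST from the strip alone (smoothed
    with the same LOWESS used before agreement statistics), build the change
    curve of the estimate and of the measured foot temperature from
    lights-off, grand-average both groups and correlate the means.
    """
    est_curves, foot_curves = [], []
    for rec in fixture.sessions_for("lab"):
        df, _gate = build_feature_table(rec, with_reference=False)
        y = predict_session(model, df)
        if y.empty:
            continue
        if smooth:
            y = smooth_estimate(y)
        foot = aggregate_minute(rec.streams["foot"],
                                n_minutes=int(rec.duration_minutes))
        foot_series = pd.Series(foot.values, index=foot.minute_index)
        try:
            est_curves.append(change_curve(y, rec.lights_off, horizon))
            foot_curves.append(change_curve(foot_series.dropna(),
                                            rec.lights_off, horizon))
        except ValueError:
            continue
    mean_e, mean_f, r, p = grand_average_and_correlate(est_curves, foot_curves)
    return VerificationResult(mean_estimated_curve=mean_e,
                              mean_foot_curve=mean_f, pearson_r=r,
                              p_value=p, n_sessions=len(est_curves))
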