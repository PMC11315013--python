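"""Two-stage distal skin temperature regressor.

Stage one maps the per-minute top-3 strip values (V1, V2, V3) to a first
DST estimate X(n) with a gradient boosted tree (XGBoost).  Because
consecutive distal temperatures are strongly correlated, stage two feeds the
rolling window X(n), ..., X(n-4) of five consecutive stage-one estimates to
a random forest, producing the final estimate Y(n).  Training is sequential:
the boosted tree is fitted first on pooled (V1, V2, V3) -> S rows, its
predictions on the same training sessions become the stage-two design
matrix, and the forest is fitted on complete windows only.  Y(n) therefore
first exists at minute 5 of a session, and any gap in valid minutes resets
the window so the next estimate appears four minutes after the gap ends.

Hyperparameters live in the discrete/continuous space of
:data:`DEFAULT_SPACE`; :func:`tune_hyperparams` searches it with a compact
tree-structured-Parzen-style sequential sampler.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

__all__ = [
    "WINDOW", "HyperparamConfig", "HyperparamSpace", "DEFAULT_SPACE",
    "DEFAULT_CONFIG", "PipelineModel", "train_sequential", "predict_session",
    "stage_two_windows", "tune_hyperparams", "TrainingError",
]

#: rolling-window length of stage two (minutes)
WINDOW = 5

FEATURES = ["V1", "V2", "V3"]


class TrainingError(RuntimeError):
    """Raised when the training data cannot support the two-stage fit."""


@dataclass(frozen=True)
class HyperparamConfig:
    """One concrete hyperparameter choice for both stages.

    ``rf_max_depth=None`` means an unbounded forest depth.
    """

    gbt_n_estimators: int = 300
    gbt_max_depth: int = 3
    gbt_learning_rate: float = 0.031
    rf_n_estimators: int = 300
    rf_max_depth: Optional[int] = None
    rf_min_samples_split: int = 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparamConfig":
        return cls(**d)


@dataclass(frozen=True)
class HyperparamSpace:
    """Search space for both stages.

    The boosted tree draws the estimator count and depth from finite sets
    and the learning rate uniformly from (0, 1); the forest draws integer
    ranges, with an explicit unbounded-depth option alongside the bounded
    depth range.
    """

    gbt_n_estimators: tuple = (100, 200, 300)
    gbt_max_depth: tuple = (3, 5, 7, 9, 15)
    gbt_learning_rate: tuple = (0.0, 1.0)
    rf_n_estimators: tuple = (10, 300)
    rf_max_depth: tuple = (1, 30)
    rf_min_samples_split: tuple = (2, 20)
    allow_unbounded_rf_depth: bool = True
    p_unbounded_depth: float = 0.2

    def sample(self, rng: np.random.Generator) -> HyperparamConfig:
        if self.allow_unbounded_rf_depth and rng.random() < self.p_unbounded_depth:
            depth: Optional[int] = None
        else:
            depth = int(rng.integers(self.rf_max_depth[0], self.rf_max_depth[1] + 1))
        return HyperparamConfig(
            gbt_n_estimators=int(rng.choice(self.gbt_n_estimators)),
            gbt_max_depth=int(rng.choice(self.gbt_max_depth)),
            gbt_learning_rate=float(rng.uniform(*self.gbt_learning_rate)),
            rf_n_estimators=int(rng.integers(self.rf_n_estimators[0],
                                             self.rf_n_estimators[1] + 1)),
            rf_max_depth=depth,
            rf_min_samples_split=int(rng.integers(self.rf_min_samples_split[0],
                                                  self.rf_min_samples_split[1] + 1)),
        )

    def contains(self, c: HyperparamConfig) -> bool:
        ok = (c.gbt_n_estimators in self.gbt_n_estimators
              and c.gbt_max_depth in self.gbt_max_depth
              and self.gbt_learning_rate[0] <= c.gbt_learning_rate <= self.gbt_learning_rate[1]
              and self.rf_n_estimators[0] <= c.rf_n_estimators <= self.rf_n_estimators[1]
              and self.rf_min_samples_split[0] <= c.rf_min_samples_split <= self.rf_min_samples_split[1])
        if c.rf_max_depth is None:
            return ok and self.allow_unbounded_rf_depth
        return ok and self.rf_max_depth[0] <= c.rf_max_depth <= self.rf_max_depth[1]


DEFAULT_SPACE = HyperparamSpace()
DEFAULT_CONFIG = HyperparamConfig()


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------

def stage_two_windows(n: np.ndarray, x: np.ndarray, s: Optional[np.ndarray] = None):
    """Build complete five-minute windows from valid stage-one estimates.

    ``n`` are the (sorted) minute indices of valid minutes, ``x`` the
    stage-one estimates at those minutes.  A window for target minute
    ``n[i]`` exists when the five minutes ``n[i]-4 .. n[i]`` are all present
    and consecutive.  Returns ``(target_minutes, W)`` (and targets ``s`` at
    those minutes when given) with ``W[j] = [X(n), X(n-1), ..., X(n-4)]``.
    """
    n = np.asarray(n)
    x = np.asarray(x, dtype=float)
    if n.size < WINDOW:
        empty = (np.array([], dtype=int), np.empty((0, WINDOW)))
        return empty if s is None else empty + (np.array([]),)
    # positions i where n[i-4..i] is a run of consecutive minutes
    consec = np.ones(n.size, dtype=bool)
    consec[1:] = np.diff(n) == 1
    run = np.zeros(n.size, dtype=int)
    for i in range(n.size):  # run length of consecutive tail ending at i
        run[i] = run[i - 1] + 1 if (i > 0 and consec[i]) else 1
    ok = run >= WINDOW
    idx = np.nonzero(ok)[0]
    W = np.column_stack([x[idx - k] for k in range(WINDOW)])  # X(n) .. X(n-4)
    if s is None:
        return n[idx], W
    return n[idx], W, np.asarray(s, dtype=float)[idx]


@dataclass
class PipelineModel:
    """A fitted two-stage estimator plus its training metadata."""

    gbt: XGBRegressor
    rf: RandomForestRegressor
    config: HyperparamConfig
    seed: int
    train_subjects: tuple = ()

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        """Serialize to a directory: native XGBoost JSON for stage one,
        per-tree structure via joblib for stage two, JSON metadata."""
        import joblib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        # booster-level persistence (the sklearn wrapper's save path is not
        # usable with current scikit-learn releases)
        self.gbt.get_booster().save_model(d / "stage1_gbt.json")
        joblib.dump(self.rf, d / "stage2_rf.joblib")
        meta = {"config": self.config.to_dict(), "seed": self.seed,
                "train_subjects": list(self.train_subjects)}
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PipelineModel":
        import joblib

        import xgboost

        d = pathlib.Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        config = HyperparamConfig.from_dict(meta["config"])
        booster = xgboost.Booster()
        booster.load_model(d / "stage1_gbt.json")
        gbt = XGBRegressor(n_estimators=config.gbt_n_estimators,
                           max_depth=config.gbt_max_depth,
                           learning_rate=config.gbt_learning_rate,
                           n_jobs=1)
        gbt._Booster = booster
        rf = joblib.load(d / "stage2_rf.joblib")
        return cls(gbt=gbt, rf=rf, config=config, seed=meta["seed"],
                   train_subjects=tuple(meta["train_subjects"]))


def _valid_rows(features: pd.DataFrame, require_reference: bool) -> pd.DataFrame:
    df = features
    rows = df[df["valid"].astype(bool)]
    if require_reference:
        rows = rows[np.isfinite(rows["S"])]
    return rows


def train_sequential(train_sessions: Sequence[pd.DataFrame],
                     config: HyperparamConfig = DEFAULT_CONFIG,
                     seed: int = 0,
                     train_subjects: Sequence[str] = ()) -> PipelineModel:
    """Fit the two stages in sequence on per-session feature tables.

    Stage one pools (V1, V2, V3) -> S rows over all training sessions.
    Its predictions on those same sessions provide the stage-two windows,
    and the forest is fitted on windows -> S(n).  Deterministic for a fixed
    seed.
    """
    pooled = []
    for df in train_sessions:
        rows = _valid_rows(df, require_reference=True)
        if len(rows):
            pooled.append(rows)
    if not pooled:
        raise TrainingError("no valid training minutes with a reference")
    all_rows = pd.concat(pooled, axis=0)

    gbt = XGBRegressor(
        n_estimators=config.gbt_n_estimators,
        max_depth=config.gbt_max_depth,
        learning_rate=config.gbt_learning_rate,
        objective="reg:squarederror",
        random_state=int(seed) % (2**31 - 1),
        n_jobs=1, verbosity=0, tree_method="hist")
    gbt.fit(all_rows[FEATURES].to_numpy(), all_rows["S"].to_numpy())

    targets, windows = [], []
    for rows in pooled:
        x = gbt.predict(rows[FEATURES].to_numpy())
        n_w, W, s_w = stage_two_windows(rows["n"].to_numpy(), x,
                                        rows["S"].to_numpy())
        if n_w.size:
            windows.append(W)
            targets.append(s_w)
    if not windows:
        raise TrainingError(
            "no session contains five consecutive valid minutes; "
            "stage two has no complete window to learn from")
    W = np.vstack(windows)
    y = np.concatenate(targets)

    rf = RandomForestRegressor(
        n_estimators=config.rf_n_estimators,
        max_depth=config.rf_max_depth,
        min_samples_split=config.rf_min_samples_split,
        random_state=(int(seed) + 1) % (2**31 - 1), n_jobs=1)
    rf.fit(W, y)
    return PipelineModel(gbt=gbt, rf=rf, config=config, seed=int(seed),
                         train_subjects=tuple(train_subjects))


def predict_session(model: PipelineModel, features: pd.DataFrame) -> pd.Series:
    """Final estimates Y(n) for one session's feature table.

    Y(n) is emitted for every minute with a complete window of five valid
    consecutive stage-one estimates; the first possible index is 5, and a
    gap in valid minutes suppresses Y until four minutes after it ends.
    Returns a Series of Y indexed by minute; empty when no window exists.
    """
    rows = _valid_rows(features, require_reference=False)
    if len(rows) < WINDOW:
        return pd.Series(dtype=float, name="Y")
    x = model.gbt.predict(rows[FEATURES].to_numpy())
    n_w, W = stage_two_windows(rows["n"].to_numpy(), x)
    if n_w.size == 0:
        return pd.Series(dtype=float, name="Y")
    y = model.rf.predict(W)
    return pd.Series(y, index=n_w, name="Y")


# ---------------------------------------------------------------------------
# sequential model-based hyperparameter search
# ---------------------------------------------------------------------------

def _split_good_bad(trials, gamma=0.25):
    losses = np.array([t[1] for t in trials])
    order = np.argsort(losses, kind="stable")
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good = [trials[i][0] for i in order[:n_good]]
    bad = [trials[i][0] for i in order[n_good:]] or good
    return good, bad


def _cat_logratio(value, good_vals, bad_vals, categories):
    k = len(categories)
    pg = (good_vals.count(value) + 1.0) / (len(good_vals) + k)
    pb = (bad_vals.count(value) + 1.0) / (len(bad_vals) + k)
    return np.log(pg / pb)


def _num_logratio(value, good_vals, bad_vals, span):
    def kde(v, pts):
        pts = np.asarray(pts, dtype=float)
        bw = max(np.std(pts), 0.05 * span)
        z = (v - pts) / bw
        return np.mean(np.exp(-0.5 * z * z)) / bw + 1e-12
    return np.log(kde(value, good_vals) / kde(value, bad_vals))


def _suggest(space: HyperparamSpace, trials, rng: np.random.Generator,
             n_candidates: int = 24) -> HyperparamConfig:
    """Parzen-style suggestion: sample candidate configs from the prior and
    keep the one whose parameters look most like the best quartile of past
    trials and least like the rest (an l(x)/g(x) ranking)."""
    good, bad = _split_good_bad(trials)
    best_cfg, best_score = None, -np.inf
    for _ in range(n_candidates):
        c = space.sample(rng)
        score = 0.0
        score += _cat_logratio(c.gbt_n_estimators,
                               [g.gbt_n_estimators for g in good],
                               [b.gbt_n_estimators for b in bad],
                               space.gbt_n_estimators)
        score += _cat_logratio(c.gbt_max_depth,
                               [g.gbt_max_depth for g in good],
                               [b.gbt_max_depth for b in bad],
                               space.gbt_max_depth)
        score += _num_logratio(c.gbt_learning_rate,
                               [g.gbt_learning_rate for g in good],
                               [b.gbt_learning_rate for b in bad], 1.0)
        score += _num_logratio(c.rf_n_estimators,
                               [g.rf_n_estimators for g in good],
                               [b.rf_n_estimators for b in bad],
                               space.rf_n_estimators[1] - space.rf_n_estimators[0])
        score += _cat_logratio(c.rf_max_depth is None,
                               [g.rf_max_depth is None for g in good],
                               [b.rf_max_depth is None for b in bad],
                               (True, False))
        if score > best_score:
            best_cfg, best_score = c, score
    return best_cfg


def tune_hyperparams(tuning_sessions: dict, space: HyperparamSpace = DEFAULT_SPACE,
                     budget: int = 30, seed: int = 0,
                     val_fraction: float = 0.25,
                     n_startup: int = 8):
    """Sequential model-based search over the hyperparameter space.

    ``tuning_sessions`` maps subject id -> list of feature tables.  Subjects
    are split 75/25 into an inner train/validation partition (whole
    subjects, honouring the subject-blocking philosophy); each trial trains
    the two-stage pipeline on the inner training subjects and scores the
    mean squared error of Y against S on the inner validation subjects.
    After ``n_startup`` random trials, new configurations are proposed by a
    Parzen-ratio rule over past trials.  Returns ``(best_config, trials)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not tuning_sessions:
        raise ValueError("tuning set is empty")
    rng = np.random.default_rng(seed)
    subjects = sorted(tuning_sessions)
    perm = rng.permutation(len(subjects))
    n_val = max(1, int(round(val_fraction * len(subjects))))
    if n_val >= len(subjects):
        raise ValueError("need at least two tuning subjects for an inner split")
    val_subjects = [subjects[i] for i in perm[:n_val]]
    train_subjects = [subjects[i] for i in perm[n_val:]]
    train_tables = [df for s in train_subjects for df in tuning_sessions[s]]
    val_tables = [df for s in val_subjects for df in tuning_sessions[s]]

    def objective(config: HyperparamConfig) -> float:
        model = train_sequential(train_tables, config,
                                 seed=int(rng.integers(2**31 - 1)))
        errs = []
        for df in val_tables:
            y = predict_session(model, df)
            if y.empty:
                continue
            s = df.set_index("n").loc[y.index, "S"]
            ok = np.isfinite(s.to_numpy())
            errs.append((s.to_numpy()[ok] - y.to_numpy()[ok]) ** 2)
        if not errs:
            return np.inf
        return float(np.mean(np.concatenate(errs)))

    trials = []
    for t in range(budget):
        if t < n_startup or len(trials) < 2:
            config = space.sample(rng)
        else:
            config = _suggest(space, trials, rng)
        trials.append((config, objective(config)))

    best = min(trials, key=lambda t: t[1])[0]
    return best, trials
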