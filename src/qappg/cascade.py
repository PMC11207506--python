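"""Cascade of binary quality classifiers that picks an algorithm per segment.

One gradient-boosted tree classifier (logistic loss) per portfolio algorithm,
each trained to answer "is this segment usable after that algorithm?".  At
inference the stages run in ascending-energy order with early exit on the
first acceptance; a segment rejected by every stage is discarded.  Stage
thresholds share a single multiplier that is bisected on validation data to
hit a target discard fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from .core_io import Segment
from .errors import CalibrationError, ContractError, DegenerateTrainingError
from .portfolio import Portfolio, outcome_vectors
from .sqi_features import FEATURE_NAMES

__all__ = [
    "DISCARD",
    "BinaryQualityClassifier",
    "CascadeModel",
    "TrainingConfig",
    "make_labels",
    "train_stage",
    "assemble_cascade",
    "select",
    "calibrate_reject_rate",
]

#: Sentinel selection for segments no stage accepts.
DISCARD = "DISCARD"

DEFAULT_GRID = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100, 200],
}

_THRESHOLD_CAP = 1.0 + 1e-9  # a threshold above 1 rejects everything


@dataclass
class TrainingConfig:
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    cv: str = "loso"  # "loso" (requires groups) or an int K for stratified K-fold
    target_reject_rate: float = 0.30
    seed: int = 0
    scoring: str = "balanced_accuracy"

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ContractError("hyperparameter grid must be non-empty")
        if not 0 <= self.target_reject_rate < 1:
            raise ContractError("target_reject_rate must be in [0, 1)")


@dataclass
class BinaryQualityClassifier:
    model: GradientBoostingClassifier
    threshold: float
    feature_names: tuple[str, ...]
    algorithm_id: str
    cv_score: float = float("nan")
    best_params: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(usable) for each row."""
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


@dataclass
class CascadeModel:
    stages: tuple[BinaryQualityClassifier, ...]
    portfolio: Portfolio
    discard_id: str = DISCARD

    def __post_init__(self) -> None:
        if tuple(s.algorithm_id for s in self.stages) != self.portfolio.ids:
            raise ContractError("stage order must match portfolio (ascending energy)")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = set(FEATURE_NAMES) - set(features.columns)
        if missing:
            raise ContractError(f"feature matrix missing columns: {sorted(missing)}")
        return features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ContractError(f"expected n x {len(FEATURE_NAMES)} feature matrix")
    return X


def make_labels(
    segments: list[Segment],
    portfolio: Portfolio,
    reference_bpm: np.ndarray,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
) -> dict[str, np.ndarray]:
    """Per-algorithm usability labels (1 = HR error after processing <= thr)."""
    vecs = outcome_vectors(segments, list(portfolio.specs), reference_bpm,
                           band=band, thr_bpm=thr_bpm)
    return {v.algorithm_id: v.bits.astype(int) for v in vecs}


def _param_grid(grid: dict):
    keys = sorted(grid)
    def rec(i):
        if i == len(keys):
            yield {}
            return
        for v in grid[keys[i]]:
            for rest in rec(i + 1):
                yield {keys[i]: v, **rest}
    return list(rec(0))


def _folds(y: np.ndarray, groups, tc: TrainingConfig):
    n = y.size
    if tc.cv == "loso":
        if groups is None:
            raise ContractError("LOSO cross-validation requires group labels")
        splitter = LeaveOneGroupOut()
        return list(splitter.split(np.zeros(n), y, groups=np.asarray(groups)))
    k = int(tc.cv)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=tc.seed)
    return list(splitter.split(np.zeros(n), y))


def train_stage(
    features,
    labels: np.ndarray,
    tc: TrainingConfig,
    groups=None,
    algorithm_id: str = "",
) -> BinaryQualityClassifier:
    """Grid-search a boosted binary classifier on subject-grouped folds.

    The grid is scored by validation balanced accuracy; folds whose training
    split is single-class are skipped.  Deterministic for a fixed seed.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateTrainingError(
            f"labels for {algorithm_id or 'stage'} contain a single class"
        )
    finite = np.all(np.isfinite(X), axis=1)
    X_fit, y_fit = X[finite], y[finite]
    groups_fit = np.asarray(groups)[finite] if groups is not None else None
    if np.unique(y_fit).size < 2:
        raise DegenerateTrainingError(
            f"labels for {algorithm_id or 'stage'} single-class after sentinel removal"
        )
    folds = _folds(y_fit, groups_fit, tc)
    best = None
    for params in _param_grid(tc.grid):
        scores = []
        for tr, va in folds:
            if np.unique(y_fit[tr]).size < 2 or va.size == 0:
                continue
            clf = GradientBoostingClassifier(loss="log_loss", random_state=tc.seed, **params)
            clf.fit(X_fit[tr], y_fit[tr])
            with warnings.catch_warnings():
                # single-class validation folds (e.g. an all-clean held-out
                # subject) degenerate to plain accuracy; that is intended
                warnings.simplefilter("ignore", UserWarning)
                scores.append(balanced_accuracy_score(y_fit[va], clf.predict(X_fit[va])))
        score = float(np.mean(scores)) if scores else float("-inf")
        if best is None or score > best[0]:
            best = (score, params)
    cv_score, best_params = best
    model = GradientBoostingClassifier(loss="log_loss", random_state=tc.seed, **best_params)
    model.fit(X_fit, y_fit)
    return BinaryQualityClassifier(
        model=model,
        threshold=0.5,
        feature_names=tuple(FEATURE_NAMES),
        algorithm_id=algorithm_id,
        cv_score=cv_score,
        best_params=best_params,
    )


def assemble_cascade(
    stages: list[BinaryQualityClassifier], portfolio: Portfolio
) -> CascadeModel:
    """Order the stages so the cheapest algorithm is evaluated first."""
    by_id = {s.algorithm_id: s for s in stages}
    if set(by_id) != set(portfolio.ids) or len(stages) != len(portfolio.ids):
        raise ContractError(
            f"stages {sorted(by_id)} do not match portfolio {sorted(portfolio.ids)}"
        )
    ordered = tuple(by_id[aid] for aid in portfolio.ids)
    return CascadeModel(stages=ordered, portfolio=portfolio)


def select(cm: CascadeModel, sqi) -> str:
    """Early-exit stage evaluation; DISCARD when every stage rejects.

    ``sqi`` is a feature mapping or vector in :data:`FEATURE_NAMES` order.
    Non-finite (sentinel) features discard immediately.
    """
    if isinstance(sqi, dict):
        x = np.array([sqi[name] for name in FEATURE_NAMES], dtype=float)
    else:
        x = np.asarray(sqi, dtype=float)
    if not np.all(np.isfinite(x)):
        return DISCARD
    row = x.reshape(1, -1)
    for stage in cm.stages:
        if stage.predict_proba(row)[0] >= stage.threshold:
            return stage.algorithm_id
    return DISCARD


def select_batch(cm: CascadeModel, features) -> np.ndarray:
    """Vectorized :func:`select` over a feature matrix."""
    X = _as_matrix(features)
    out = np.full(X.shape[0], DISCARD, dtype=object)
    finite = np.all(np.isfinite(X), axis=1)
    undecided = finite.copy()
    for stage in cm.stages:
        if not undecided.any():
            break
        idx = np.flatnonzero(undecided)
        accept = stage.predict_proba(X[idx]) >= stage.threshold
        out[idx[accept]] = stage.algorithm_id
        undecided[idx[accept]] = False
    return out


def _reject_fraction(cm: CascadeModel, X: np.ndarray, multiplier: float) -> float:
    finite = np.all(np.isfinite(X), axis=1)
    rejected = np.ones(X.shape[0], dtype=bool)
    rejected[~finite] = True
    idx = np.flatnonzero(finite)
    undecided = idx
    for stage in cm.stages:
        if undecided.size == 0:
            break
        thr = min(stage.threshold * multiplier, _THRESHOLD_CAP)
        accept = stage.predict_proba(X[undecided]) >= thr
        rejected[undecided[accept]] = False
        undecided = undecided[~accept]
    return float(np.mean(rejected))


def calibrate_reject_rate(
    cm: CascadeModel,
    features,
    target: float,
    tol: float = 0.02,
    max_iter: int = 60,
) -> CascadeModel:
    """Scale all stage thresholds by one bisected multiplier so the validation
    discard fraction lands within ``tol`` of ``target``."""
    if not 0 <= target < 1:
        raise ContractError("target reject rate must be in [0, 1)")
    X = _as_matrix(features)
    if X.shape[0] == 0:
        raise ContractError("validation set must be non-empty")

    lo, hi = 0.0, _THRESHOLD_CAP / min(s.threshold for s in cm.stages)
    f_lo = _reject_fraction(cm, X, lo)
    f_hi = _reject_fraction(cm, X, hi)
    if not (f_lo - tol <= target <= f_hi + tol):
        raise CalibrationError(
            f"target {target:.2f} outside attainable reject range [{f_lo:.2f}, {f_hi:.2f}]"
        )
    best_m, best_gap, best_f = 1.0, float("inf"), f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _reject_fraction(cm, X, mid)
        gap = abs(f - target)
        if gap < best_gap:
            best_m, best_gap, best_f = mid, gap, f
        if f < target:
            lo = mid
        else:
            hi = mid
    if best_f >= 1.0 and target < 1.0:
        # a multiplier that discards every validation segment is never a
        # usable operating point
        raise CalibrationError(
            f"reject target {target:.2f} only reachable by discarding everything"
        )
    if best_gap > tol:
        raise CalibrationError(
            f"could not reach reject rate {target:.2f} +/- {tol:.2f} "
            f"(best {best_gap + target:.2f} off by {best_gap:.3f})"
        )
    new_stages = tuple(
        BinaryQualityClassifier(
            model=s.model,
            threshold=min(s.threshold * best_m, _THRESHOLD_CAP),
            feature_names=s.feature_names,
            algorithm_id=s.algorithm_id,
            cv_score=s.cv_score,
            best_params=s.best_params,
        )
        for s in cm.stages
    )
    return CascadeModel(stages=new_stages, portfolio=cm.portfolio)


def save_cascade(cm: CascadeModel, directory: str | Path, seed: int | None = None) -> None:
    """Serialize as per-stage model files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage_order": list(cm.portfolio.ids),
        "thresholds": [s.threshold for s in cm.stages],
        "feature_names": list(FEATURE_NAMES),
        "portfolio": cm.portfolio.to_dict(),
        "seed": seed,
    }
    for stage in cm.stages:
        joblib.dump(stage.model, directory / f"stage_{stage.algorithm_id}.joblib")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
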