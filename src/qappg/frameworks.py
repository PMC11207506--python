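"""End-to-end framework runners: OFA, SQA and QAP, plus group analysis.

* OFA (one-for-all): every segment processed by one fixed algorithm.
* SQA (signal quality assessment): a single quality classifier scores the raw
  segments and the worst fraction is discarded; nothing is processed.
* QAP (quality-aware processing): the cascade selects a portfolio algorithm
  (or DISCARD) per segment from its raw-signal quality indices.

Energy is accounted declaratively: OFA pays only the algorithm's per-segment
cost; SQA pays the quality-assessment overhead; QAP pays the overhead plus
the selected algorithm's cost (overhead only for discarded segments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from . import algorithms as alg
from .cascade import DISCARD, CascadeModel, select_batch
from .core_io import Segment
from .errors import ContractError
from .hr_estimation import estimate_hr_ppg, metrics
from .portfolio import EnergyModel
from .sqi_features import feature_matrix

__all__ = [
    "FrameworkReport",
    "GroupReport",
    "run_ofa",
    "run_sqa",
    "run_qap",
    "group_analysis",
    "compare",
    "train_sqa_classifier",
]

GROUP_NAMES = ("I", "II", "III", "IV")


@dataclass
class FrameworkReport:
    framework: str
    accuracy_pct: float
    mae_bpm: float
    mae_std_bpm: float
    rmse_bpm: float
    energy_per_segment_mJ: float
    reject_pct: float
    selection_distribution: dict[str, float]
    n_retained: int
    n_total: int
    full_set_metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.selection_distribution.values()) + self.reject_pct / 100.0
        if abs(total - 1.0) > 1e-9:
            raise ContractError("selection fractions plus reject must sum to 1")
        if self.framework == "OFA" and self.reject_pct != 0:
            raise ContractError("OFA never rejects")

    def to_dict(self) -> dict:
        return {
            "framework": self.framework,
            "accuracy_pct": self.accuracy_pct,
            "mae_bpm": self.mae_bpm,
            "mae_std_bpm": self.mae_std_bpm,
            "rmse_bpm": self.rmse_bpm,
            "energy_per_segment_mJ": self.energy_per_segment_mJ,
            "reject_pct": self.reject_pct,
            "selection_distribution": dict(self.selection_distribution),
            "n_retained": self.n_retained,
            "n_total": self.n_total,
            "full_set_metrics": dict(self.full_set_metrics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameworkReport":
        return cls(**d)


@dataclass
class GroupReport:
    """No-processing accuracy/MAE per cascade selection group."""

    groups: dict[str, dict]

    def to_dict(self) -> dict:
        return {"groups": self.groups}


def _estimates(
    segments: list[Segment], spec: alg.AlgorithmSpec | None,
    band: tuple[float, float],
) -> np.ndarray:
    est = np.full(len(segments), np.nan)
    for i, seg in enumerate(segments):
        try:
            processed = alg.apply(seg, spec) if spec is not None else seg
            est[i] = estimate_hr_ppg(processed, band=band).bpm
        except Exception:
            est[i] = np.nan
    return est


def _finalize(
    framework: str,
    est: np.ndarray,
    references: np.ndarray,
    retained: np.ndarray,
    energy: float,
    selection: dict[str, float],
    thr_bpm: float,
) -> FrameworkReport:
    ref = np.asarray(references, dtype=float)
    usable = retained & np.isfinite(est) & np.isfinite(ref)
    m = metrics(np.nan_to_num(est), np.nan_to_num(ref), usable, thr_bpm=thr_bpm)
    full_ok = np.isfinite(est) & np.isfinite(ref)
    full = metrics(np.nan_to_num(est), np.nan_to_num(ref), full_ok, thr_bpm=thr_bpm) \
        if full_ok.any() else {}
    reject_pct = 100.0 * (1.0 - retained.mean())
    return FrameworkReport(
        framework=framework,
        accuracy_pct=m["accuracy_pct"],
        mae_bpm=m["mae_bpm"],
        mae_std_bpm=m["mae_std_bpm"],
        rmse_bpm=m["rmse_bpm"],
        energy_per_segment_mJ=energy,
        reject_pct=reject_pct,
        selection_distribution=selection,
        n_retained=int(usable.sum()),
        n_total=len(est),
        full_set_metrics=full,
    )


def run_ofa(
    segments: list[Segment],
    algorithm_id: str,
    references: np.ndarray,
    em: EnergyModel | None = None,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
    pool: list[alg.AlgorithmSpec] | None = None,
) -> FrameworkReport:
    """Process every segment with one algorithm; no quality assessment."""
    em = em or EnergyModel()
    spec = alg.get_spec(algorithm_id, pool)
    est = _estimates(segments, spec, band)
    retained = np.ones(len(segments), dtype=bool)
    energy = em.per_algorithm_mJ[algorithm_id]
    return _finalize("OFA", est, references, retained, energy,
                     {algorithm_id: 1.0}, thr_bpm)


def train_sqa_classifier(
    features: pd.DataFrame, bypass_labels: np.ndarray, seed: int = 0
) -> GradientBoostingClassifier:
    """Single raw-signal quality classifier (usable-under-bypass labels)."""
    X = features.to_numpy(dtype=float)
    finite = np.all(np.isfinite(X), axis=1)
    clf = GradientBoostingClassifier(loss="log_loss", random_state=seed)
    clf.fit(X[finite], np.asarray(bypass_labels)[finite])
    return clf


def run_sqa(
    segments: list[Segment],
    references: np.ndarray,
    reject_rate: float,
    quality_clf: GradientBoostingClassifier,
    em: EnergyModel | None = None,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
    features: pd.DataFrame | None = None,
) -> FrameworkReport:
    """Discard the lowest-scoring fraction; estimate the rest on the raw signal."""
    em = em or EnergyModel()
    if features is None:
        features = feature_matrix(segments)
    X = features.to_numpy(dtype=float)
    scores = np.full(len(segments), -np.inf)
    finite = np.all(np.isfinite(X), axis=1)
    if finite.any():
        scores[finite] = quality_clf.predict_proba(X[finite])[:, 1]
    n_reject = int(round(reject_rate * len(segments)))
    retained = np.ones(len(segments), dtype=bool)
    if n_reject > 0:
        retained[np.argsort(scores)[:n_reject]] = False
    est = _estimates(segments, None, band)
    energy = em.sqa_overhead_mJ
    bypass_frac = float(retained.mean())
    return _finalize("SQA", est, references, retained, energy,
                     {"BYPASS": bypass_frac}, thr_bpm)


def run_qap(
    segments: list[Segment],
    references: np.ndarray,
    cascade: CascadeModel,
    em: EnergyModel | None = None,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
    features: pd.DataFrame | None = None,
) -> tuple[FrameworkReport, np.ndarray]:
    """Per-segment cascade selection, processing and estimation.

    Returns the report plus the raw selection array (used by group analysis).
    """
    em = em or EnergyModel()
    if features is None:
        features = feature_matrix(segments)
    selections = select_batch(cascade, features)
    specs = {s.id: s for s in cascade.portfolio.specs}
    est = np.full(len(segments), np.nan)
    for i, seg in enumerate(segments):
        if selections[i] == DISCARD:
            continue
        try:
            processed = alg.apply(seg, specs[selections[i]])
            est[i] = estimate_hr_ppg(processed, band=band).bpm
        except Exception:
            est[i] = np.nan
    retained = selections != DISCARD
    n = len(segments)
    selection_dist = {
        aid: float(np.mean(selections == aid)) for aid in cascade.portfolio.ids
    }
    energy = em.sqa_overhead_mJ + sum(
        selection_dist[aid] * em.per_algorithm_mJ.get(aid, specs[aid].energy_mJ)
        for aid in cascade.portfolio.ids
    )
    report = _finalize("QAP", est, references, retained, energy, selection_dist, thr_bpm)
    return report, selections


def group_analysis(
    selections: np.ndarray,
    segments: list[Segment],
    references: np.ndarray,
    cascade: CascadeModel,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
) -> GroupReport:
    """No-processing accuracy per selection group (I = cheapest ... IV = discard)."""
    ids = list(cascade.portfolio.ids) + [DISCARD]
    est = _estimates(segments, None, band)
    ref = np.asarray(references, dtype=float)
    groups: dict[str, dict] = {}
    for name, aid in zip(GROUP_NAMES, ids):
        mask = (selections == aid) & np.isfinite(est) & np.isfinite(ref)
        count = int(np.sum(selections == aid))
        if not mask.any():
            groups[name] = {"algorithm_id": aid, "count": count,
                            "accuracy_pct": None, "mae_bpm": None}
            continue
        m = metrics(np.nan_to_num(est), np.nan_to_num(ref), mask, thr_bpm=thr_bpm)
        groups[name] = {
            "algorithm_id": aid,
            "count": count,
            "accuracy_pct": m["accuracy_pct"],
            "mae_bpm": m["mae_bpm"],
            "mae_std_bpm": m["mae_std_bpm"],
        }
    return GroupReport(groups=groups)


def compare(reports: list[FrameworkReport]) -> tuple[str, str]:
    """Aligned comparison table; returns ``(text_table, json_payload)``."""
    if len(reports) < 2:
        raise ContractError("compare needs at least two reports")
    rows = ["accuracy_pct", "mae_bpm", "mae_std_bpm", "rmse_bpm",
            "energy_per_segment_mJ", "reject_pct"]
    headers = [
        f"{r.framework}({'+'.join(r.selection_distribution)})" for r in reports
    ]
    df = pd.DataFrame(
        {h: [getattr(r, row) for row in rows] for h, r in zip(headers, reports)},
        index=rows,
    )
    payload = json.dumps([r.to_dict() for r in reports], indent=2)
    return df.to_string(float_format=lambda v: f"{v:.2f}"), payload
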