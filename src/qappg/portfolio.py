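"""Outcome vectors, hamming similarity and energy-budgeted portfolio formation.

Each candidate algorithm gets a binary outcome vector over the labeled
segments (1 = segment usable after that algorithm's processing).  Normalized
hamming distance between vectors measures behavioral dissimilarity; a greedy
search seeded with BYPASS picks up to three mutually dissimilar algorithms
from the subset that fits the energy budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import algorithms as alg
from .core_io import Segment
from .errors import ConfigurationError, ContractError
from .hr_estimation import estimate_hr_ppg, usability_label

__all__ = [
    "OutcomeVector",
    "DistanceMatrix",
    "EnergyModel",
    "Portfolio",
    "ONE_FOR_ALL",
    "normalized_hamming",
    "outcome_vectors",
    "distance_matrix",
    "filter_by_budget",
    "form_portfolio",
    "admissibility_threshold",
]

#: Sentinel returned by budget filtering when the mechanism itself is
#: inadmissible (budget below the quality-assessment overhead).
ONE_FOR_ALL = "one-for-all"

DEFAULT_SQA_OVERHEAD_MJ = 35.536


@dataclass(frozen=True)
class OutcomeVector:
    algorithm_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(bits, (0, 1)).all():
            raise ContractError("outcome bits must be binary")
        object.__setattr__(self, "bits", bits)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ContractError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ContractError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "d", d)

    def dist(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


@dataclass
class EnergyModel:
    """Per-segment energy bookkeeping for budget filtering and reporting."""

    per_algorithm_mJ: dict[str, float] = field(
        default_factory=lambda: dict(alg.DEFAULT_ENERGY_MJ)
    )
    sqa_overhead_mJ: float = DEFAULT_SQA_OVERHEAD_MJ
    classifier_overhead_mJ: float = 0.0
    budget_mJ: float = float("inf")

    def __post_init__(self) -> None:
        if self.sqa_overhead_mJ < 0 or self.classifier_overhead_mJ < 0:
            raise ConfigurationError("overheads must be >= 0")
        if any(v < 0 for v in self.per_algorithm_mJ.values()):
            raise ConfigurationError("per-algorithm energies must be >= 0")


@dataclass(frozen=True)
class Portfolio:
    """Up to three algorithm specs, strictly ordered by ascending energy."""

    specs: tuple[alg.AlgorithmSpec, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.specs) <= 3:
            raise ContractError("portfolio holds between 1 and 3 algorithms")
        energies = [s.energy_mJ for s in self.specs]
        if energies != sorted(energies):
            raise ContractError("portfolio must be ordered by ascending energy")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.specs)

    def mean_pairwise_distance(self, dm: DistanceMatrix) -> float:
        ids = self.ids
        if len(ids) < 2:
            return 0.0
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        return float(np.mean([dm.dist(ids[i], ids[j]) for i, j in pairs]))

    def to_dict(self, dm: DistanceMatrix | None = None) -> dict:
        out = {
            "ids": list(self.ids),
            "energies_mJ": [s.energy_mJ for s in self.specs],
        }
        if dm is not None:
            out["mean_pairwise_distance"] = self.mean_pairwise_distance(dm)
        return out


def normalized_hamming(u, v) -> float:
    """Fraction of positions where two equal-length binary vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.size == 0:
        raise ContractError(f"vectors must have equal nonzero length, got {u.shape} vs {v.shape}")
    return float(np.mean(u != v))


def outcome_vectors(
    segments: list[Segment],
    pool: list[alg.AlgorithmSpec],
    reference_bpm: np.ndarray,
    band: tuple[float, float] = (0.83, 2.16),
    thr_bpm: float = 5.0,
) -> list[OutcomeVector]:
    """Process every segment with every algorithm and record usability bits.

    Segments whose reference is missing (NaN) are dropped from every vector so
    the vectors stay index-aligned.
    """
    reference_bpm = np.asarray(reference_bpm, dtype=float)
    if len(segments) != reference_bpm.size:
        raise ContractError("segments and references must align")
    valid = np.isfinite(reference_bpm)
    segs = [s for s, ok in zip(segments, valid) if ok]
    refs = reference_bpm[valid]
    if not segs:
        raise ContractError("no segments with available reference")
    vectors = []
    for spec in pool:
        bits = np.zeros(len(segs), dtype=np.int8)
        for i, (seg, ref) in enumerate(zip(segs, refs)):
            try:
                est = estimate_hr_ppg(alg.apply(seg, spec), band=band)
                bits[i] = usability_label(est.bpm, ref, thr_bpm).value
            except Exception:
                bits[i] = 0
        vectors.append(OutcomeVector(algorithm_id=spec.id, bits=bits))
    return vectors


def distance_matrix(vectors: list[OutcomeVector]) -> DistanceMatrix:
    ids = tuple(v.algorithm_id for v in vectors)
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = normalized_hamming(vectors[i].bits, vectors[j].bits)
    return DistanceMatrix(ids=ids, d=d)


def filter_by_budget(pool: list[alg.AlgorithmSpec], em: EnergyModel):
    """Admit algorithms whose energy plus the assessment overhead fits the budget.

    Returns the admitted sub-pool, or the :data:`ONE_FOR_ALL` sentinel when
    the budget cannot even cover the mechanism's own overhead.
    """
    if em.budget_mJ < em.sqa_overhead_mJ:
        return ONE_FOR_ALL
    return [
        s for s in pool
        if em.sqa_overhead_mJ + em.per_algorithm_mJ.get(s.id, s.energy_mJ) <= em.budget_mJ
    ]


def admissibility_threshold(algorithm_id: str, em: EnergyModel) -> float:
    """Smallest budget at which the algorithm passes :func:`filter_by_budget`."""
    if algorithm_id not in em.per_algorithm_mJ:
        raise ConfigurationError(f"no energy configured for {algorithm_id!r}")
    return em.sqa_overhead_mJ + em.per_algorithm_mJ[algorithm_id]


def form_portfolio(
    admitted: list[alg.AlgorithmSpec],
    dm: DistanceMatrix,
    size: int = 3,
) -> Portfolio:
    """Greedy diversity maximization seeded with BYPASS.

    Repeatedly add the candidate with the highest mean hamming distance to the
    already-selected set (ties: lower energy, then id) until ``size``
    algorithms are selected or the pool is exhausted; the result is ordered by
    ascending energy.
    """
    by_id = {s.id: s for s in admitted}
    if "BYPASS" not in by_id:
        raise ContractError("admitted pool must contain BYPASS")
    missing = set(by_id) - set(dm.ids)
    if missing:
        raise ContractError(f"distance matrix does not cover: {sorted(missing)}")
    selected = ["BYPASS"]
    while len(selected) < size:
        candidates = [aid for aid in by_id if aid not in selected]
        if not candidates:
            break
        scored = [
            (-np.mean([dm.dist(c, s) for s in selected]), by_id[c].energy_mJ, c)
            for c in candidates
        ]
        scored.sort()
        selected.append(scored[0][2])
    specs = sorted((by_id[aid] for aid in selected), key=lambda s: s.energy_mJ)
    return Portfolio(specs=tuple(specs))
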