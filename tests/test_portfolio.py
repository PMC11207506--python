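import itertools

import numpy as np
import pytest

from qappg import algorithms as alg
from qappg.errors import ConfigurationError, ContractError
from qappg.portfolio import (
    DistanceMatrix,
    EnergyModel,
    ONE_FOR_ALL,
    OutcomeVector,
    Portfolio,
    admissibility_threshold,
    distance_matrix,
    filter_by_budget,
    form_portfolio,
    normalized_hamming,
    outcome_vectors,
)

# Published reference distances between the processed-outcome vectors of the
# nine pool algorithms (lower = more similar behavior).
_REF_IDS = ("BYPASS", "BPF", "EMD", "CUB", "SSA", "WVL", "SVDTFD", "HPF", "LPF")
_REF_LOWER = {
    ("LPF", "BYPASS"): 0.001, ("LPF", "BPF"): 0.162, ("LPF", "EMD"): 0.152,
    ("LPF", "CUB"): 0.163, ("LPF", "SSA"): 0.197, ("LPF", "WVL"): 0.152,
    ("LPF", "SVDTFD"): 0.166, ("LPF", "HPF"): 0.161,
    ("HPF", "BYPASS"): 0.162, ("HPF", "BPF"): 0.021, ("HPF", "EMD"): 0.059,
    ("HPF", "CUB"): 0.080, ("HPF", "SSA"): 0.090, ("HPF", "WVL"): 0.037,
    ("HPF", "SVDTFD"): 0.040,
    ("SVDTFD", "BYPASS"): 0.167, ("SVDTFD", "BPF"): 0.032, ("SVDTFD", "EMD"): 0.066,
    ("SVDTFD", "CUB"): 0.079, ("SVDTFD", "SSA"): 0.095, ("SVDTFD", "WVL"): 0.053,
    ("WVL", "BYPASS"): 0.180, ("WVL", "BPF"): 0.042, ("WVL", "EMD"): 0.041,
    ("WVL", "CUB"): 0.074, ("WVL", "SSA"): 0.097,
    ("SSA", "BYPASS"): 0.198, ("SSA", "BPF"): 0.091, ("SSA", "EMD"): 0.107,
    ("SSA", "CUB"): 0.103,
    ("CUB", "BYPASS"): 0.164, ("CUB", "BPF"): 0.079, ("CUB", "EMD"): 0.091,
    ("EMD", "BYPASS"): 0.153, ("EMD", "BPF"): 0.064,
    ("BPF", "BYPASS"): 0.163,
}


def reference_dm() -> DistanceMatrix:
    n = len(_REF_IDS)
    d = np.zeros((n, n))
    for (a, b), v in _REF_LOWER.items():
        i, j = _REF_IDS.index(a), _REF_IDS.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=_REF_IDS, d=d)


class TestNormalizedHamming:
    def test_worked_example_one_eighth(self):
        u = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        v = np.array([1, 0, 1, 1, 0, 0, 0, 0])
        assert normalized_hamming(u, v) == 0.125

    def test_identity(self, rng):
        u = rng.integers(0, 2, size=20)
        assert normalized_hamming(u, u) == 0.0

    def test_complement(self, rng):
        u = rng.integers(0, 2, size=17)
        assert normalized_hamming(u, 1 - u) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            normalized_hamming([1, 0], [1, 0, 1])

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            normalized_hamming([], [])

    def test_metric_axioms_exhaustive_small(self):
        # identity + symmetry + triangle inequality, exhaustive for n <= 4
        for n in range(1, 5):
            vectors = list(itertools.product([0, 1], repeat=n))
            for u in vectors:
                assert normalized_hamming(u, u) == 0.0
            for u, v in itertools.combinations(vectors, 2):
                duv = normalized_hamming(u, v)
                assert duv == normalized_hamming(v, u)
                assert duv > 0
            for u, v, w in itertools.combinations(vectors, 3):
                assert normalized_hamming(u, w) <= (
                    normalized_hamming(u, v) + normalized_hamming(v, w) + 1e-12
                )

    def test_metric_axioms_sampled_n10(self, rng):
        for _ in range(2000):
            u, v, w = rng.integers(0, 2, size=(3, 10))
            assert normalized_hamming(u, w) <= (
                normalized_hamming(u, v) + normalized_hamming(v, w) + 1e-12
            )


class TestEnergyModel:
    def test_defaults(self):
        em = EnergyModel()
        assert em.sqa_overhead_mJ == 35.536
        assert em.per_algorithm_mJ["SSA"] == 28767.42

    def test_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            EnergyModel(sqa_overhead_mJ=-1.0)


class TestFilterByBudget:
    def test_budget_100(self):
        pool = alg.list_pool()
        admitted = filter_by_budget(pool, EnergyModel(budget_mJ=100.0))
        ids = {s.id for s in admitted}
        assert ids == {"BYPASS", "WVL", "BPF", "LPF", "CUB", "HPF"}

    def test_budget_below_overhead(self):
        assert filter_by_budget(alg.list_pool(), EnergyModel(budget_mJ=30.0)) == ONE_FOR_ALL

    def test_infinite_budget(self):
        admitted = filter_by_budget(alg.list_pool(), EnergyModel(budget_mJ=float("inf")))
        assert len(admitted) == 9


class TestAdmissibilityThreshold:
    def test_svd(self):
        assert admissibility_threshold("SVDTFD", EnergyModel()) == pytest.approx(368.57, abs=0.01)

    def test_ssa(self):
        assert admissibility_threshold("SSA", EnergyModel()) == pytest.approx(28802.96, abs=0.01)

    def test_bypass_is_overhead(self):
        assert admissibility_threshold("BYPASS", EnergyModel()) == pytest.approx(35.54, abs=0.01)

    def test_threshold_consistent_with_filter(self):
        em = EnergyModel()
        for aid in ("BPF", "SVDTFD", "SSA"):
            thr = admissibility_threshold(aid, em)
            em_lo = EnergyModel(budget_mJ=thr - 0.005)
            em_hi = EnergyModel(budget_mJ=thr + 0.005)
            assert aid not in {s.id for s in filter_by_budget(alg.list_pool(), em_lo)}
            assert aid in {s.id for s in filter_by_budget(alg.list_pool(), em_hi)}

    def test_unknown_id(self):
        with pytest.raises(ConfigurationError):
            admissibility_threshold("NOPE", EnergyModel())


def _toy_dm(ids, entries):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=tuple(ids), d=d)


def _brute_force_greedy(ids, dmat, energies, size=3):
    """Independent re-statement of the greedy rule for oracle comparison."""
    selected = ["BYPASS"]
    while len(selected) < size:
        best = None
        for c in ids:
            if c in selected:
                continue
            score = sum(dmat[ids.index(c)][ids.index(s)] for s in selected) / len(selected)
            key = (-score, energies[c], c)
            if best is None or key < best[0]:
                best = (key, c)
        if best is None:
            break
        selected.append(best[1])
    return sorted(selected, key=lambda a: (energies[a], a))


class TestFormPortfolio:
    def test_toy_hand_trace(self):
        # d(bypass,A)=0.3 > d(bypass,B)=0.2, then B added; order by energy
        ids = ["BYPASS", "BPF", "CUB"]  # use BPF as "A", CUB as "B"
        dm = _toy_dm(ids, {("BYPASS", "BPF"): 0.3, ("BYPASS", "CUB"): 0.2,
                           ("BPF", "CUB"): 0.1})
        pool = [alg.get_spec(a) for a in ids]
        pf = form_portfolio(pool, dm)
        assert pf.ids == ("BYPASS", "BPF", "CUB")  # BPF 10.05 < CUB 10.85

    def test_pool_exhausted(self):
        ids = ["BYPASS", "BPF"]
        dm = _toy_dm(ids, {("BYPASS", "BPF"): 0.5})
        pf = form_portfolio([alg.get_spec(a) for a in ids], dm)
        assert pf.ids == ("BYPASS", "BPF")

    def test_missing_bypass(self):
        ids = ["BPF", "CUB"]
        dm = _toy_dm(ids, {("BPF", "CUB"): 0.5})
        with pytest.raises(ContractError):
            form_portfolio([alg.get_spec(a) for a in ids], dm)

    def test_reference_distances_first_pick_is_ssa(self):
        dm = reference_dm()
        pool = alg.list_pool()
        pf = form_portfolio(pool, dm, size=2)
        assert "SSA" in pf.ids  # greatest distance from bypass (0.198)

    def test_matches_brute_force_on_random_pools(self, rng):
        pool_specs = alg.list_pool()
        energies = {s.id: s.energy_mJ for s in pool_specs}
        for _ in range(200):
            k = rng.integers(2, 7)
            others = list(rng.choice([s.id for s in pool_specs if s.id != "BYPASS"],
                                     size=k - 1, replace=False))
            ids = ["BYPASS"] + others
            n = len(ids)
            m = np.round(rng.uniform(0, 1, size=(n, n)), 3)
            d = np.triu(m, 1)
            d = d + d.T
            dm = DistanceMatrix(ids=tuple(ids), d=d)
            pf = form_portfolio([alg.get_spec(a) for a in ids], dm)
            expected = _brute_force_greedy(ids, d, energies)
            assert list(pf.ids) == expected

    def test_greedy_diversity_beats_worst_random(self, rng):
        """Mean pairwise distance of the greedy pick >= worst random 3-subset
        containing BYPASS on >= 95% of random matrices."""
        ids = list(alg.ALGORITHM_IDS)
        pool = alg.list_pool()
        wins = 0
        trials = 100
        for _ in range(trials):
            m = rng.uniform(0, 1, size=(9, 9))
            d = np.triu(m, 1)
            d = d + d.T
            dm = DistanceMatrix(ids=tuple(ids), d=d)
            pf = form_portfolio(pool, dm)
            greedy_div = pf.mean_pairwise_distance(dm)
            worst = min(
                np.mean([dm.dist(a, b) for a, b in itertools.combinations(subset, 2)])
                for subset in itertools.combinations(ids, 3)
                if "BYPASS" in subset
            )
            if greedy_div >= worst - 1e-12:
                wins += 1
        assert wins / trials >= 0.95


class TestOutcomeVectors:
    def test_clean_corpus_bypass_all_ones(self, clean_session):
        segs = clean_session.segments()
        refs = clean_session.truth.true_hr_bpm
        vecs = outcome_vectors(segs, [alg.get_spec("BYPASS")], refs)
        assert vecs[0].bits.tolist() == [1] * len(segs)

    def test_empty_segments_rejected(self):
        with pytest.raises(ContractError):
            outcome_vectors([], [alg.get_spec("BYPASS")], np.array([]))

    def test_duplicate_algorithm_zero_distance(self, clean_session):
        segs = clean_session.segments()
        refs = clean_session.truth.true_hr_bpm
        vecs = outcome_vectors(segs, [alg.get_spec("BPF"), alg.get_spec("BPF")], refs)
        assert normalized_hamming(vecs[0].bits, vecs[1].bits) == 0.0

    def test_nan_reference_dropped_aligned(self, clean_session):
        segs = clean_session.segments()
        refs = clean_session.truth.true_hr_bpm.copy()
        refs[1] = np.nan
        vecs = outcome_vectors(segs, [alg.get_spec("BYPASS"), alg.get_spec("BPF")], refs)
        assert all(v.bits.size == len(segs) - 1 for v in vecs)


class TestTypes:
    def test_portfolio_ordering_enforced(self):
        specs = (alg.get_spec("CUB"), alg.get_spec("BYPASS"))  # wrong order
        with pytest.raises(ContractError):
            Portfolio(specs=specs)

    def test_portfolio_max_three(self):
        specs = tuple(alg.get_spec(a) for a in ("BYPASS", "WVL", "BPF", "LPF"))
        with pytest.raises(ContractError):
            Portfolio(specs=specs)

    def test_outcome_vector_binary_only(self):
        with pytest.raises(ContractError):
            OutcomeVector(algorithm_id="BPF", bits=np.array([0, 2, 1]))

    def test_distance_matrix_symmetry_enforced(self):
        with pytest.raises(ContractError):
            DistanceMatrix(ids=("a", "b"), d=np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_distance_matrix_export(self):
        dm = reference_dm()
        df = dm.to_frame()
        assert df.loc["SSA", "BYPASS"] == 0.198
        assert df.shape == (9, 9)
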