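"""Hypergeometric scoring, acceptability filtering and candidate ranking."""

from fractions import Fraction

import numpy as np
import pytest

from causaltf import (
    MODELS,
    ConfigurationError,
    DEGSet,
    StatisticalError,
    UnknownIdentifierError,
    acceptable_models,
    all_downstream_sets,
    correctly_identified,
    hypergeom_overlap_pvalue,
    rank_candidates,
    score_all,
    score_tf,
)
from causaltf.downstream_models import DownstreamSets
from causaltf.enrichment import EnrichmentResult, ModelAcceptability, ModelScore

from _oracle import hypergeom_tail_enumerate, hypergeom_tail_fraction


def make_sets(tf, genes):
    """DownstreamSets with every model equal to ``genes`` (flat TF)."""
    s = frozenset(genes)
    return DownstreamSets(tf=tf, sets={m: s for m in MODELS}, mediators={m: {} for m in MODELS})


def make_result(tf, p_by_model, k=1, K=5, n=10, N=100):
    scores = {m: ModelScore(K=K, k=k, p=p) for m, p in p_by_model.items()}
    return EnrichmentResult(tf=tf, scores=scores, n=n, N=N)


class TestHypergeomTail:
    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap_pvalue(0, 5, 10, 100) == 1.0

    def test_exact_enumeration_small_draws(self):
        # all C(10,3) draws, counted literally
        assert hypergeom_tail_enumerate(3, 3, 3, 10) == Fraction(1, 120)
        assert hypergeom_tail_enumerate(1, 3, 3, 10) == Fraction(85, 120)
        assert hypergeom_overlap_pvalue(3, 3, 3, 10) == pytest.approx(1 / 120, rel=1e-12)
        assert hypergeom_overlap_pvalue(1, 3, 3, 10) == pytest.approx(85 / 120, rel=1e-12)

    def test_matches_rational_oracle_everywhere_small(self):
        for N in (1, 2, 5, 11, 18, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(hypergeom_tail_fraction(k, K, n, N))
                        got = hypergeom_overlap_pvalue(k, K, n, N)
                        assert got == pytest.approx(expected, abs=1e-12), (k, K, n, N)

    def test_strictly_decreasing_in_k(self):
        for K, n, N in [(5, 10, 100), (20, 30, 200), (3, 3, 10)]:
            ps = [hypergeom_overlap_pvalue(k, K, n, N) for k in range(min(K, n) + 1)]
            for a, b in zip(ps, ps[1:]):
                if a < 1:
                    assert b < a

    def test_gaussian_tail_envelope(self):
        # far-tail sanity at scale: within a factor of 3 of the normal tail
        from scipy import stats

        N, K, n = 10_000, 1_000, 1_000
        mean = n * K / N
        sd = np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        k = int(round(mean + 4 * sd))
        p = hypergeom_overlap_pvalue(k, K, n, N)
        z = (k - 0.5 - mean) / sd  # continuity-corrected
        gauss = stats.norm.sf(z)
        assert gauss / 3 < p < gauss * 3

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            hypergeom_overlap_pvalue(6, 5, 10, 100)
        with pytest.raises(ConfigurationError):
            hypergeom_overlap_pvalue(1, 101, 10, 100)


class TestScoreTF:
    def test_counts_and_universe_restriction(self, fig2):
        universe = frozenset(f"g{i}" for i in range(1, 9)) | frozenset(
            f"u{i}" for i in range(92)
        )
        degs = DEGSet(genes=frozenset(f"g{i}" for i in range(1, 9)))
        res = score_tf(all_downstream_sets(fig2, "A"), degs, universe)
        assert res.n == 8 and res.N == 100
        assert res.scores["I"].k == 3 and res.scores["I"].K == 3
        assert res.scores["VI"].k == 8 and res.scores["VI"].K == 8
        # Model VI captures all 8 DEGs vs 3 for Model I
        assert res.p("VI") < res.p("I")

    def test_perfect_overlap_attains_minimum(self):
        universe = frozenset(f"x{i}" for i in range(50))
        target = frozenset(list(sorted(universe))[:6])
        res = score_tf(make_sets("T", target), DEGSet(genes=target), universe)
        floor = hypergeom_overlap_pvalue(6, 6, 6, 50)
        assert res.p("I") == pytest.approx(floor)
        for k in range(6):
            assert hypergeom_overlap_pvalue(k, 6, 6, 50) > floor

    def test_disjoint_gives_one(self):
        universe = frozenset(f"x{i}" for i in range(20))
        res = score_tf(
            make_sets("T", {"x0", "x1"}), DEGSet(genes=frozenset({"x10", "x11"})), universe
        )
        assert all(res.p(m) == 1.0 for m in MODELS)

    def test_empty_degs_warns_all_one(self, caplog):
        universe = frozenset({"x0", "x1", "x2"})
        with caplog.at_level("WARNING"):
            res = score_tf(make_sets("T", {"x0"}), DEGSet(genes=frozenset()), universe)
        assert all(res.p(m) == 1.0 for m in MODELS)
        assert any("empty DEG set" in r.message for r in caplog.records)

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            score_tf(make_sets("T", set()), DEGSet(genes=frozenset()), frozenset())


class TestAcceptability:
    def test_identical_distributions_acceptable(self):
        results = [
            make_result(f"T{i}", {m: 0.1 * (i + 1) for m in MODELS}) for i in range(10)
        ]
        acc = acceptable_models(results)
        assert acc.acceptable_models == MODELS
        assert all(acc.ranksum_p[m] == 1.0 or acc.ranksum_p[m] > 0.9 for m in MODELS[1:])

    def test_all_tied_pvalues_acceptable(self):
        results = [make_result(f"T{i}", {m: 1.0 for m in MODELS}) for i in range(5)]
        acc = acceptable_models(results)
        assert all(acc.ranksum_p[m] == 1.0 for m in MODELS)

    def test_shifted_model_rejected_consistently(self):
        rejected = 0
        trials = 200
        for trial in range(trials):
            rng = np.random.default_rng(trial)
            p_i = rng.uniform(size=100)
            results = []
            for i, p in enumerate(p_i):
                by_model = {m: p for m in MODELS}
                by_model["IV"] = p / 1000
                results.append(make_result(f"T{i}", by_model))
            acc = acceptable_models(results, alpha=0.005)
            if not acc.acceptable("IV"):
                rejected += 1
            assert acc.acceptable("II")  # untouched model stays acceptable
        assert rejected / trials > 0.99

    def test_alpha_zero_accepts_everything(self):
        rng = np.random.default_rng(0)
        results = [
            make_result(f"T{i}", {m: rng.uniform() for m in MODELS}) for i in range(30)
        ]
        acc = acceptable_models(results, alpha=0.0)
        assert acc.acceptable_models == MODELS

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        results = []
        transformed = []
        for i in range(40):
            ps = {m: rng.uniform() for m in MODELS}
            ps["III"] = ps["III"] / 50
            results.append(make_result(f"T{i}", ps))
            transformed.append(make_result(f"T{i}", {m: p**2 for m, p in ps.items()}))
        a = acceptable_models(results)
        b = acceptable_models(transformed)
        for m in MODELS:
            assert a.ranksum_p[m] == pytest.approx(b.ranksum_p[m])

    def test_too_few_tfs(self):
        with pytest.raises(StatisticalError):
            acceptable_models([make_result("T0", {m: 0.5 for m in MODELS})])


class TestRanking:
    def acc_all(self):
        return ModelAcceptability(ranksum_p={m: 1.0 for m in MODELS})

    def test_min_selection_and_masking(self):
        ps = {"I": 0.02, "II": 1e-6, "III": 0.5, "IV": 0.9, "V": 0.7, "VI": 0.6}
        res = [make_result("T0", ps), make_result("T1", {m: 0.8 for m in MODELS})]
        ranked = rank_candidates(res, self.acc_all())
        assert ranked[0].tf == "T0"
        assert ranked[0].best_model == "II"
        assert ranked[0].min_p == pytest.approx(1e-6)
        # same TF when Model II is unacceptable falls back to Model I
        masked = ModelAcceptability(
            ranksum_p={m: (0.0 if m == "II" else 1.0) for m in MODELS}
        )
        ranked2 = rank_candidates(res, masked)
        assert ranked2[0].best_model == "I"
        assert ranked2[0].min_p == pytest.approx(0.02)

    def test_forced_winner(self):
        universe = frozenset(f"x{i}" for i in range(60))
        degs = frozenset(list(sorted(universe))[:5])
        sets = [make_sets("HIT", degs)]
        decoys = sorted(universe - degs)
        for i in range(9):
            sets.append(make_sets(f"D{i}", decoys[5 * i : 5 * i + 5]))
        results = score_all(sets, DEGSet(genes=degs), universe)
        ranked = rank_candidates(results, acceptable_models(results))
        assert ranked[0].tf == "HIT" and ranked[0].valid

    def test_tie_break_lower_model_then_overlap_then_name(self):
        tie = {m: 0.5 for m in MODELS}
        r1 = make_result("B", tie, k=3)
        r2 = make_result("A", tie, k=3)
        r3 = make_result("C", tie, k=7)
        ranked = rank_candidates([r1, r2, r3], self.acc_all())
        assert [r.tf for r in ranked] == ["C", "A", "B"]  # larger k first, then name
        assert all(r.best_model == "I" for r in ranked)
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        results = [
            make_result(f"T{i}", {m: rng.uniform() for m in MODELS}, k=i % 5)
            for i in range(25)
        ]
        acc = self.acc_all()
        ranked = rank_candidates(results, acc)
        shuffled = list(results)
        rng.shuffle(shuffled)
        assert rank_candidates(shuffled, acc) == ranked

    def test_empty_results(self):
        assert rank_candidates([], self.acc_all()) == []


class TestCorrectlyIdentified:
    def make_ranked(self, entries):
        from causaltf import RankedCandidate

        return [
            RankedCandidate(
                tf=tf, rank=rank, best_model="I", min_p=p, k_best=1, K_best=2,
                n=10, N=100, valid=p <= 0.01,
            )
            for tf, rank, p in entries
        ]

    def test_gates(self):
        ranked = self.make_ranked([("T0", 1, 1e-8), ("T1", 22, 1e-8), ("T2", 5, 0.02)])
        assert correctly_identified(ranked, "T0")
        assert not correctly_identified(ranked, "T1")  # beyond the top-20 window
        assert not correctly_identified(ranked, "T2")  # not a valid finding
        assert correctly_identified(ranked, "T1", top_k=25)

    def test_unknown_tf(self):
        with pytest.raises(UnknownIdentifierError):
            correctly_identified(self.make_ranked([("T0", 1, 0.5)]), "missing")
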