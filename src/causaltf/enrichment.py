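"""Hypergeometric overlap scoring, model acceptability filtering and ranking.

For a candidate TF with expected-target set T_m under model m, the overlap
with the observed DEG set D is scored by the hypergeometric upper tail

    p_m = P(X >= k),   X ~ Hypergeometric(N, K, n)

with K = |T_m ∩ U|, n = |D|, N = |U| and k = |T_m ∩ D| for a gene universe
U. Considering richer models can only help the perturbed TF if it does not
also inflate every other TF's significance, so a model m is *acceptable*
only when the distribution of its overlap p-values across all candidate TFs
is not significantly different from Model I's (two-sample Wilcoxon rank-sum
test, p > alpha, default alpha 0.005); Model I is always acceptable. Each TF
is then ranked by its minimum p-value over the acceptable models, and is a
*valid finding* when that minimum is <= 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, StatisticalError, UnknownIdentifierError
from .regnet_io import DEGSet
from .downstream_models import MODELS, DownstreamSets

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    """Overlap of one model's expected targets with the DEG set."""

    K: int  # expected-target set size (within the universe)
    k: int  # overlap count with the DEGs
    p: float  # hypergeometric upper-tail p-value


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-model overlap scores for one TF against one DEG set."""

    tf: str
    scores: Mapping[str, ModelScore]  # model id -> score
    n: int  # DEG count
    N: int  # universe size

    def p(self, model: str) -> float:
        return self.scores[model].p


@dataclass(frozen=True)
class ModelAcceptability:
    """Which models survive the rank-sum comparison against Model I."""

    ranksum_p: Mapping[str, float]  # model id -> rank-sum test p (Model I: 1.0)
    alpha: float = 0.005

    def acceptable(self, model: str) -> bool:
        return model == "I" or self.ranksum_p[model] > self.alpha

    @property
    def acceptable_models(self) -> tuple[str, ...]:
        return tuple(m for m in MODELS if self.acceptable(m))


@dataclass(frozen=True)
class RankedCandidate:
    """One TF's position in the causal-regulator ranking."""

    tf: str
    rank: int  # 1-based
    best_model: str  # acceptable model attaining the minimum p
    min_p: float  # minimum p over acceptable models
    k_best: int
    K_best: int
    n: int
    N: int
    valid: bool  # min_p <= valid-finding threshold


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def hypergeom_overlap_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts how many of ``n`` draws (the DEGs), taken without
    replacement from a universe of ``N`` genes containing ``K`` expected
    targets, fall among the expected targets. Returns 1.0 at k = 0.
    """
    if not (0 <= k <= min(K, n)):
        raise ConfigurationError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or N < 0:
        raise ConfigurationError(f"inconsistent sizes K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy's parametrisation is (M=N, n=K, N=n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    # guard against tiny negative round-off; the tail includes X = k so p > 0
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def score_tf(
    sets: DownstreamSets,
    degs: DEGSet,
    universe: Iterable[str],
) -> EnrichmentResult:
    """Score all six model sets of one TF against the DEG set.

    Model sets are intersected with the universe before scoring; the DEG set
    must be contained in the universe. An empty DEG set yields p = 1 for
    every model (with a warning) rather than an error, so empty contrasts
    flow through batch runs.
    """
    uni = frozenset(universe)
    if not uni:
        raise ConfigurationError("empty gene universe")
    if not degs.genes <= uni:
        stray = sorted(degs.genes - uni)[:5]
        raise ConfigurationError(f"DEGs outside the universe, e.g. {stray}")
    n = len(degs.genes)
    N = len(uni)
    if n == 0:
        logger.warning("empty DEG set: all overlap p-values are 1 for %s", sets.tf)
    scores = {}
    for model in MODELS:
        t_m = sets.sets[model] & uni
        k = len(t_m & degs.genes)
        scores[model] = ModelScore(K=len(t_m), k=k, p=hypergeom_overlap_pvalue(k, len(t_m), n, N))
    return EnrichmentResult(tf=sets.tf, scores=scores, n=n, N=N)


def score_all(
    sets_collection: Iterable[DownstreamSets],
    degs: DEGSet,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    uni = frozenset(universe)
    return [score_tf(s, degs, uni) for s in sets_collection]


# ---------------------------------------------------------------------------
# Acceptability filter
# ---------------------------------------------------------------------------

def _ranksum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Two-sample Wilcoxon rank-sum p-value with degenerate-tie guard."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # every observation tied: no evidence of a shift
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) < 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # mid-ranks, normal approximation, tie correction
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def acceptable_models(
    all_results: Sequence[EnrichmentResult],
    alpha: float = 0.005,
    alternative: str = "two-sided",
) -> ModelAcceptability:
    """Filter models by comparing their p-value distributions to Model I's.

    For each model m != I the candidate-wide vectors {p_I} and {p_m} are
    compared by an unpaired Wilcoxon rank-sum test; m is acceptable when the
    test p-value exceeds ``alpha``. ``alternative`` may be ``"two-sided"``
    (default: any distributional shift disqualifies) or ``"greater"``
    (only a shift of p_m toward smaller values — p_I stochastically greater
    — disqualifies).
    """
    if len(all_results) < 2:
        raise StatisticalError(
            "acceptability filtering needs p-values from at least 2 candidate TFs"
        )
    if alternative not in ("two-sided", "greater"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    p_i = np.array([r.p("I") for r in all_results])
    ranksum_p = {"I": 1.0}
    for model in MODELS[1:]:
        p_m = np.array([r.p(model) for r in all_results])
        ranksum_p[model] = _ranksum_p(p_i, p_m, alternative)
    return ModelAcceptability(ranksum_p=ranksum_p, alpha=alpha)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_candidates(
    all_results: Sequence[EnrichmentResult],
    acceptability: ModelAcceptability,
    valid_p: float = 0.01,
) -> list[RankedCandidate]:
    """Rank TFs by their minimum p-value over the acceptable models.

    The best model is the acceptable model attaining the minimum (ties go to
    the lower-numbered model). TFs are sorted by ascending minimum p; ties
    are broken by larger overlap count at the best model, then by TF
    identifier. ``valid`` flags TFs at or below the valid-finding threshold
    (default p <= 0.01).
    """
    keyed = []
    for res in all_results:
        best_model = min(
            acceptability.acceptable_models,
            key=lambda m: (res.p(m), MODELS.index(m)),
        )
        best = res.scores[best_model]
        keyed.append((best.p, -best.k, res.tf, best_model, best, res))
    keyed.sort()
    out = []
    for rank, (min_p, _neg_k, tf, best_model, best, res) in enumerate(keyed, start=1):
        out.append(
            RankedCandidate(
                tf=tf,
                rank=rank,
                best_model=best_model,
                min_p=min_p,
                k_best=best.k,
                K_best=best.K,
                n=res.n,
                N=res.N,
                valid=min_p <= valid_p,
            )
        )
    return out


def correctly_identified(
    ranked: Sequence[RankedCandidate],
    true_tf: str,
    top_k: int = 20,
    p_threshold: float = 0.01,
) -> bool:
    """Was the actually perturbed TF a valid finding within the top ranks?

    True iff ``true_tf``'s minimum acceptable-model p-value is at or below
    ``p_threshold`` and its rank is within ``top_k``.
    """
    by_tf = {r.tf: r for r in ranked}
    if true_tf not in by_tf:
        raise UnknownIdentifierError(f"{true_tf!r} is not among the ranked candidates")
    cand = by_tf[true_tf]
    return cand.min_p <= p_threshold and cand.rank <= top_k


def ranking_to_frame(
    ranked: Sequence[RankedCandidate],
    acceptability: Optional[ModelAcceptability] = None,
) -> pd.DataFrame:
    """Tabular view of a ranking (one row per TF, best model first)."""
    rows = []
    acc = (
        ",".join(acceptability.acceptable_models) if acceptability is not None else ""
    )
    for r in ranked:
        rows.append(
            {
                "rank": r.rank,
                "tf": r.tf,
                "best_model": r.best_model,
                "min_p": r.min_p,
                "k_best": r.k_best,
                "K_best": r.K_best,
                "n": r.n,
                "N": r.N,
                "valid": r.valid,
                "acceptable_models": acc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "tf", "best_model", "min_p", "k_best", "K_best",
            "n", "N", "valid", "acceptable_models",
        ],
    )


def acceptability_to_frame(acceptability: ModelAcceptability) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": m,
                "ranksum_p": acceptability.ranksum_p[m],
                "acceptable": acceptability.acceptable(m),
            }
            for m in MODELS
        ]
    )
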