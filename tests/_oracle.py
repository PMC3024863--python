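"""Independent oracles used by the test suite.

Deliberately naive implementations: the downstream-set oracle enumerates
admissible role-constrained mediator paths one node at a time, and the
hypergeometric oracle works in exact rational arithmetic (with a literal
draw-enumeration variant for tiny universes). Neither shares code with the
package's implementations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

# Mediator-chain grammars, one list of hop sequences per model. Each hop is
# (edge kind, node constraint); the terminal transcription hop to the
# downstream gene is implicit after the chain.
_CHAINS = {
    "I": [[]],
    "II": [[], [("ptm", "tf")]],
    "III": [[], [("ptm", "tf")], [("trans", "tf")], [("ptm", "tf"), ("trans", "tf")]],
    "IV": [[], [("ptm", "tf")], [("trans", "any"), ("modulator", "tf")]],
}
_CHAINS["V"] = _CHAINS["III"] + _CHAINS["IV"][2:]
_CHAINS["VI"] = _CHAINS["V"] + [[("trans", "tf"), ("trans", "tf")]]


def _step(net, node, kind):
    if kind == "trans":
        return set(net.transcription.get(node, ()))
    pairs = net.modification.get(node, ())
    if kind == "ptm":
        return {t for t, sk in pairs if sk in ("kinase", "phosphatase")}
    if kind == "modulator":
        return {t for t, sk in pairs if sk == "modulator"}
    raise ValueError(kind)


def brute_force_downstream(net, tf, model):
    """Downstream genes of ``tf`` by exhaustive role-path enumeration."""
    genes: set[str] = set()
    for chain in _CHAINS[model]:
        paths = [[tf]]
        for kind, constraint in chain:
            grown = []
            for path in paths:
                for nxt in _step(net, path[-1], kind):
                    if nxt in path:  # a role is filled at most once per path
                        continue
                    if constraint == "tf" and nxt not in net.tf_roster:
                        continue
                    grown.append(path + [nxt])
            paths = grown
        for path in paths:
            genes |= _step(net, path[-1], "trans")
    return frozenset(genes)


def hypergeom_tail_fraction(k, K, n, N) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(hits, total)


def hypergeom_tail_enumerate(k, K, n, N) -> Fraction:
    """Same tail by literally enumerating all C(N, n) draws (tiny N only)."""
    marked = set(range(K))
    favorable = sum(
        1 for draw in itertools.combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return Fraction(favorable, comb(N, n))
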