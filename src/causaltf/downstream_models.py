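"""The six hierarchical downstream gene-set models of a transcription factor.

A TF can affect a gene's expression directly (by binding its promoter),
indirectly through a transcriptional cascade (the TF transcribes another TF,
which transcribes the gene), or post-translationally (the TF — or a
"modulator" protein the TF transcribes — modifies another TF whose targets
then change). Six nested model topologies capture these routes, bounded so
that the path from the focal TF to the last TF in the chain has length at
most 2 (longer chains blur the downstream sets of distinct TFs together):

=====  ==================================  ============================================
model  label                               downstream genes of focal TF A
=====  ==================================  ============================================
I      simple direct                       direct transcription targets of A
II     PTM-mediated direct                 I + targets of TFs B that A phosphorylates/
                                           dephosphorylates
III    two-layer cascade                   II + targets of TFs C transcribed by A and
                                           of TFs D transcribed by any B
IV     PTM-mediated two-layer cascade      II + targets of TFs E modified by a
                                           modulator X that A transcribes
V      hybrid two-layer cascade            III + IV
VI     three-layer cascade                 V + targets of TFs F transcribed by any C
=====  ==================================  ============================================

Mediator roles B, C, D, E, F must be in the TF roster; X may be any protein
transcribed by the focal TF. The focal TF never mediates for itself, a role
is never filled by the protein that reached it (no self-loops in a chain),
and mediators reached only through modification edges (B, E) contribute
their targets without themselves becoming downstream genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .regnet_io import RegulatoryNetwork

MODELS = ("I", "II", "III", "IV", "V", "VI")

MODEL_LABELS = {
    "I": "simple direct",
    "II": "PTM-mediated direct",
    "III": "two-layer cascade",
    "IV": "PTM-mediated two-layer cascade",
    "V": "hybrid two-layer cascade",
    "VI": "three-layer cascade",
}

MEDIATOR_RELATIONS = ("ptm_substrate", "transcribed_tf", "modulator_modified")

#: roles whose members are used by each model (for mediator bookkeeping)
_MODEL_ROLES = {
    "I": (),
    "II": ("B",),
    "III": ("B", "C", "D"),
    "IV": ("B", "X", "E"),
    "V": ("B", "C", "D", "X", "E"),
    "VI": ("B", "C", "D", "X", "E", "F"),
}


@dataclass(frozen=True)
class DownstreamSets:
    """The six expected-target sets of one TF plus the mediators used.

    ``sets`` maps a model id to the downstream gene set (the K-set of the
    enrichment test); ``mediators`` maps a model id to its role bindings
    (role letter -> proteins filling that role).
    """

    tf: str
    sets: Mapping[str, frozenset[str]]
    mediators: Mapping[str, Mapping[str, frozenset[str]]]

    def max_size(self) -> int:
        return max(len(s) for s in self.sets.values())


def direct_targets(net: RegulatoryNetwork, regulator: str) -> frozenset[str]:
    """Transcription targets of ``regulator`` (Model I set when a TF)."""
    return net.targets(regulator)


def mediator_tfs(net: RegulatoryNetwork, tf: str, relation: str) -> frozenset[str]:
    """Mediating TFs reachable from ``tf`` by one admissible hop.

    ``ptm_substrate``: roster TFs that ``tf`` modifies by a kinase or
    phosphatase edge (role B). ``transcribed_tf``: roster TFs among the
    transcription targets of ``tf`` (role C). ``modulator_modified``: roster
    TFs modified, via a modulator-subkind edge, by any protein X that ``tf``
    transcribes (role E). The focal TF is excluded from every mediator set
    and self-edges are ignored.
    """
    if relation == "ptm_substrate":
        pool = net.ptm_substrates(tf)
        return frozenset(p for p in pool if net.is_tf(p) and p != tf)
    if relation == "transcribed_tf":
        return frozenset(t for t in net.targets(tf) if net.is_tf(t) and t != tf)
    if relation == "modulator_modified":
        out: set[str] = set()
        for x in net.targets(tf):
            if x == tf:
                continue
            out.update(
                e
                for e in net.modulator_substrates(x)
                if net.is_tf(e) and e not in (tf, x)
            )
        return frozenset(out)
    raise ConfigurationError(f"unknown mediator relation {relation!r}")


def _roles(net: RegulatoryNetwork, tf: str) -> dict[str, frozenset[str]]:
    """All role bindings for ``tf``: B, C, D, E, F and modulator X."""
    b = mediator_tfs(net, tf, "ptm_substrate")
    c = mediator_tfs(net, tf, "transcribed_tf")
    e = mediator_tfs(net, tf, "modulator_modified")
    x = frozenset(
        p
        for p in net.targets(tf)
        if p != tf
        and any(net.is_tf(s) and s not in (tf, p) for s in net.modulator_substrates(p))
    )
    d = frozenset(
        t
        for m in b
        for t in net.targets(m)
        if net.is_tf(t) and t not in (tf, m)
    )
    f = frozenset(
        t
        for m in c
        for t in net.targets(m)
        if net.is_tf(t) and t not in (tf, m)
    )
    return {"B": b, "C": c, "D": d, "E": e, "F": f, "X": x}


def _union_targets(net: RegulatoryNetwork, regulators: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for r in regulators:
        out.update(net.targets(r))
    return out


def downstream_set(net: RegulatoryNetwork, tf: str, model: str) -> frozenset[str]:
    """The expected-target gene set of ``tf`` under one model topology."""
    if model not in MODELS:
        raise ConfigurationError(f"unknown model id {model!r}")
    roles = _roles(net, tf)
    return _downstream_set(net, tf, model, roles)


def _downstream_set(
    net: RegulatoryNetwork, tf: str, model: str, roles: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    set_i = set(net.targets(tf))
    if model == "I":
        return frozenset(set_i)
    set_ii = set_i | _union_targets(net, roles["B"])
    if model == "II":
        return frozenset(set_ii)
    if model in ("III", "V", "VI"):
        set_iii = set_ii | _union_targets(net, roles["C"]) | _union_targets(net, roles["D"])
        if model == "III":
            return frozenset(set_iii)
    if model in ("IV", "V", "VI"):
        set_iv = set_ii | _union_targets(net, roles["E"])
        if model == "IV":
            return frozenset(set_iv)
    set_v = set_iii | set_iv
    if model == "V":
        return frozenset(set_v)
    return frozenset(set_v | _union_targets(net, roles["F"]))


def all_downstream_sets(net: RegulatoryNetwork, tf: str) -> DownstreamSets:
    """All six model sets of ``tf`` with mediator bookkeeping."""
    roles = _roles(net, tf)
    sets = {m: _downstream_set(net, tf, m, roles) for m in MODELS}
    mediators = {
        m: {role: roles[role] for role in _MODEL_ROLES[m]} for m in MODELS
    }
    return DownstreamSets(tf=tf, sets=sets, mediators=mediators)


def candidate_tfs(net: RegulatoryNetwork, min_size: int = 4) -> frozenset[str]:
    """TFs whose largest model set reaches ``min_size`` genes.

    Small downstream sets make the overlap test powerless, so TFs with fewer
    than ``min_size`` (default 4) downstream genes in every model are
    dropped from the candidate list.
    """
    if min_size < 1:
        raise ConfigurationError("min_size must be >= 1")
    return frozenset(
        tf
        for tf in net.tf_roster
        if all_downstream_sets(net, tf).max_size() >= min_size
    )


def mediators_to_frame(sets_collection: Iterable[DownstreamSets]) -> pd.DataFrame:
    """Long-format mediator table: (tf, model, role, mediator)."""
    rows = [
        (sets.tf, model, role, mediator)
        for sets in sets_collection
        for model in MODELS
        for role in _MODEL_ROLES[model]
        for mediator in sorted(sets.mediators[model][role])
    ]
    return pd.DataFrame(rows, columns=["tf", "model", "role", "mediator"])
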