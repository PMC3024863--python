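"""Input/output for regulatory-network tables, gene lists and expression data.

Edge tables are tab-separated with a header row naming at least ``source`` and
``target`` columns; ``score`` (log-likelihood score of a TF-DNA interaction)
and ``subkind`` (``kinase``/``phosphatase``/``modulator`` for modification
edges) are optional. Gene sets are exchanged in GMT format, gene lists as one
identifier per line. Identifiers are case-preserving and matched exactly; no
alias resolution is attempted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    UnknownIdentifierError,
    ValidationError,
)

logger = logging.getLogger(__name__)

TRANSCRIPTION = "transcription"
MODIFICATION = "modification"
EDGE_KINDS = (TRANSCRIPTION, MODIFICATION)

KINASE = "kinase"
PHOSPHATASE = "phosphatase"
MODULATOR = "modulator"
PTM_SUBKINDS = (KINASE, PHOSPHATASE)
MOD_SUBKINDS = (KINASE, PHOSPHATASE, MODULATOR)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeRecord:
    """One directed edge: ``source`` regulates/modifies ``target``."""

    source: str
    target: str
    score: Optional[float] = None
    subkind: Optional[str] = None


@dataclass(frozen=True)
class EdgeList:
    """A homogeneous list of edges of one kind, deduplicated, in load order."""

    kind: str
    records: tuple[EdgeRecord, ...]

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ConfigurationError(f"unknown edge kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Criterion:
    """A DEG-selection rule: which statistic, which threshold, how compared.

    ``mode`` is ``"le"`` (statistic <= threshold, used for p-values) or
    ``"abs_ge"`` (|statistic| >= threshold, used for z-scores and fold
    changes). Thresholds are inclusive.
    """

    statistic: str
    threshold: float
    mode: str

    def matches(self, value: float) -> bool:
        if self.mode == "le":
            return value <= self.threshold
        if self.mode == "abs_ge":
            return abs(value) >= self.threshold
        raise ConfigurationError(f"unknown criterion mode {self.mode!r}")


def p_le(alpha: float = 0.01) -> Criterion:
    """DEGs are genes with p-value <= alpha (default 0.01)."""
    return Criterion("p_value", alpha, "le")


def abs_z_ge(tau: float = 2.0) -> Criterion:
    """DEGs are genes with |z-score| >= tau (default 2)."""
    return Criterion("z_score", tau, "abs_ge")


def abs_fold_ge(phi: float = 2.0) -> Criterion:
    """DEGs (or gold TFs) are genes with |signed fold change| >= phi."""
    return Criterion("fold_change", phi, "abs_ge")


@dataclass(frozen=True)
class DEGSet:
    """The observed set D of differentially expressed genes."""

    genes: frozenset[str]
    criterion: Optional[Criterion] = None
    measured_universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.measured_universe is not None and not self.genes <= self.measured_universe:
            missing = sorted(self.genes - self.measured_universe)[:5]
            raise ValidationError(
                f"DEGs outside the measured universe, e.g. {missing}"
            )


class ExpressionProfile:
    """Per-gene expression statistics (fold change, p-value, z-score).

    Wraps a DataFrame indexed by gene identifier with any subset of the
    columns ``fold_change``, ``p_value``, ``z_score``. One row per gene;
    p-values, when present, must lie in [0, 1].
    """

    STAT_COLUMNS = ("fold_change", "p_value", "z_score")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate gene records, e.g. {dupes}")
        if "p_value" in frame.columns:
            p = frame["p_value"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValidationError("p-values outside [0, 1]")
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Mapping[str, Mapping[str, float]]
    ) -> "ExpressionProfile":
        """Build from ``{gene: {"p_value": ..., "z_score": ..., ...}}``."""
        frame = pd.DataFrame.from_dict(records, orient="index")
        frame.index.name = "gene"
        return cls(frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionProfile":
        frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
        if "gene" not in frame.columns:
            raise ParseError(f"{path}: expression table needs a 'gene' column")
        frame["gene"] = frame["gene"].str.strip()
        return cls(frame.set_index("gene"))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    def statistic(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise ConfigurationError(
                f"expression profile has no {name!r} column "
                f"(available: {sorted(self.frame.columns)})"
            )
        return self.frame[name]


class RegulatoryNetwork:
    """Typed directed edges over proteins/genes with a TF roster.

    ``transcription`` maps a regulator to the genes it transcribes (the
    TF-DNA layer); ``modification`` maps a modifier protein to
    ``(substrate, subkind)`` pairs (the PTM layer). TF-coding genes carry a
    single identifier serving as both gene and protein, so a transcription
    target may itself be a TF in the roster.
    """

    def __init__(
        self,
        tf_roster: Iterable[str],
        transcription: Mapping[str, Iterable[str]],
        modification: Mapping[str, Iterable[tuple[str, str]]],
    ):
        self.tf_roster = frozenset(tf_roster)
        self.transcription = {
            src: frozenset(targets) for src, targets in transcription.items()
        }
        self.modification = {
            src: tuple(dict.fromkeys(pairs)) for src, pairs in modification.items()
        }
        nodes = set(self.tf_roster)
        for src, targets in self.transcription.items():
            nodes.add(src)
            nodes.update(targets)
        for src, pairs in self.modification.items():
            nodes.add(src)
            nodes.update(t for t, _ in pairs)
        self.nodes = frozenset(nodes)

    @property
    def gene_universe(self) -> frozenset[str]:
        """Union of all transcription-edge targets (recomputed on demand)."""
        out: set[str] = set()
        for targets in self.transcription.values():
            out.update(targets)
        return frozenset(out)

    def _check(self, identifier: str) -> None:
        if identifier not in self.nodes:
            raise UnknownIdentifierError(f"unknown identifier {identifier!r}")

    def targets(self, regulator: str) -> frozenset[str]:
        """Transcription targets of ``regulator`` (empty if none)."""
        self._check(regulator)
        return self.transcription.get(regulator, frozenset())

    def substrates(self, modifier: str, subkinds: Sequence[str]) -> frozenset[str]:
        """Proteins that ``modifier`` modifies via the given edge subkinds."""
        self._check(modifier)
        return frozenset(
            t for t, sk in self.modification.get(modifier, ()) if sk in subkinds
        )

    def ptm_substrates(self, modifier: str) -> frozenset[str]:
        return self.substrates(modifier, PTM_SUBKINDS)

    def modulator_substrates(self, modifier: str) -> frozenset[str]:
        return self.substrates(modifier, (MODULATOR,))

    def is_tf(self, identifier: str) -> bool:
        return identifier in self.tf_roster


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_interaction_table(
    path: str | Path,
    kind: str,
    score_threshold: Optional[float] = None,
    default_subkind: Optional[str] = None,
) -> EdgeList:
    """Load a tab-separated edge table.

    Columns are resolved by header name: ``source`` and ``target`` are
    required, ``score`` and ``subkind`` optional. When ``score_threshold`` is
    given only records with score strictly greater than the threshold are
    kept (the convention for log-likelihood-scored TF-DNA interactions, e.g.
    LLS > 4). Duplicate (source, target, subkind) records are dropped,
    keeping the first; load order is otherwise retained.
    """
    if kind not in EDGE_KINDS:
        raise ConfigurationError(f"unknown edge kind {kind!r}")
    if score_threshold is not None and kind != TRANSCRIPTION:
        raise ConfigurationError("score thresholds apply to transcription edges only")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row") from None
        header = [h.strip() for h in header]
        try:
            i_src = header.index("source")
            i_tgt = header.index("target")
        except ValueError:
            raise ParseError(
                f"{path}: header must name 'source' and 'target' columns, "
                f"got {header}"
            ) from None
        i_score = header.index("score") if "score" in header else None
        i_sub = header.index("subkind") if "subkind" in header else None
        if score_threshold is not None and i_score is None:
            raise ConfigurationError(
                f"{path}: score_threshold given but table has no 'score' column"
            )

        records: list[EdgeRecord] = []
        seen: set[tuple[str, str, Optional[str]]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}"
                )
            source = row[i_src].strip()
            target = row[i_tgt].strip()
            if not source or not target:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            score: Optional[float] = None
            if kind == TRANSCRIPTION and i_score is not None:
                cell = row[i_score].strip()
                if cell:
                    try:
                        score = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: unparseable score {cell!r}"
                        ) from None
                elif score_threshold is not None:
                    raise ParseError(
                        f"{path}:{lineno}: missing score under score thresholding"
                    )
            subkind: Optional[str] = None
            if kind == MODIFICATION:
                if i_sub is not None and row[i_sub].strip():
                    subkind = row[i_sub].strip()
                else:
                    subkind = default_subkind
                if subkind is not None and subkind not in MOD_SUBKINDS:
                    raise ParseError(
                        f"{path}:{lineno}: unknown subkind {subkind!r}"
                    )
            if score_threshold is not None and not (score > score_threshold):
                continue
            key = (source, target, subkind)
            if key in seen:
                continue
            seen.add(key)
            records.append(EdgeRecord(source, target, score, subkind))
    return EdgeList(kind=kind, records=tuple(records))


def build_network(
    tf_dna: EdgeList,
    ptm_edges: EdgeList,
    modulator_edges: EdgeList,
    tf_roster: Iterable[str],
) -> RegulatoryNetwork:
    """Merge TF-DNA and PTM edge lists into a validated network.

    Every transcription-edge source must be in ``tf_roster``; kinase/
    phosphatase edges come from ``ptm_edges``, modulator edges from
    ``modulator_edges`` (records with no subkind default to ``modulator``
    there). Records with the same endpoints but different subkinds are kept
    as distinct edges.
    """
    roster = frozenset(str(t) for t in tf_roster)
    if tf_dna.kind != TRANSCRIPTION:
        raise ValidationError("tf_dna edge list must have kind=transcription")
    for el, allowed, label in (
        (ptm_edges, PTM_SUBKINDS, "ptm_edges"),
        (modulator_edges, (MODULATOR,), "modulator_edges"),
    ):
        if el.kind != MODIFICATION:
            raise ValidationError(f"{label} must have kind=modification")

    offenders = sorted({r.source for r in tf_dna.records} - roster)
    if offenders:
        raise ValidationError(
            "transcription-edge sources missing from the TF roster: "
            + ", ".join(offenders)
        )

    transcription: dict[str, set[str]] = {}
    for rec in tf_dna.records:
        transcription.setdefault(rec.source, set()).add(rec.target)

    modification: dict[str, list[tuple[str, str]]] = {}
    for rec in ptm_edges.records:
        if rec.subkind not in PTM_SUBKINDS:
            raise ValidationError(
                f"PTM edge {rec.source}->{rec.target} needs subkind in "
                f"{PTM_SUBKINDS}, got {rec.subkind!r}"
            )
        modification.setdefault(rec.source, []).append((rec.target, rec.subkind))
    for rec in modulator_edges.records:
        subkind = rec.subkind or MODULATOR
        if subkind != MODULATOR:
            raise ValidationError(
                f"modulator edge {rec.source}->{rec.target} has subkind "
                f"{rec.subkind!r}"
            )
        modification.setdefault(rec.source, []).append((rec.target, MODULATOR))

    return RegulatoryNetwork(roster, transcription, modification)


def select_degs(profile: ExpressionProfile, criterion: Criterion) -> DEGSet:
    """Select DEGs from an expression profile by an inclusive threshold.

    The named statistic must be present (non-missing) for every profiled
    gene. The measured universe of the returned set is all profiled genes.
    """
    values = profile.statistic(criterion.statistic)
    if values.isna().any():
        missing = values.index[values.isna()].tolist()[:5]
        raise ConfigurationError(
            f"criterion statistic {criterion.statistic!r} missing for some "
            f"genes, e.g. {missing}"
        )
    genes = frozenset(g for g, v in values.items() if criterion.matches(v))
    return DEGSet(
        genes=genes,
        criterion=criterion,
        measured_universe=profile.genes,
    )


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One identifier per line; ``#`` comment lines ignored; deduplicated."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line)
    return frozenset(out)


# ---------------------------------------------------------------------------
# GMT gene-set export
# ---------------------------------------------------------------------------

def write_gene_sets_gmt(sets_collection: Iterable, path: str | Path) -> None:
    """Write per-(TF, model) downstream gene sets as GMT.

    One line per set: name ``<TF>|<model>``, description = model label, then
    member genes, all tab-separated. Genes are written sorted so output is
    deterministic.
    """
    from .downstream_models import MODEL_LABELS, MODELS  # local to avoid cycle

    with open(path, "w") as fh:
        for sets in sets_collection:
            if not sets.tf:
                raise ValidationError("downstream sets with an empty TF name")
            for model in MODELS:
                genes = sorted(sets.sets[model])
                fields = [f"{sets.tf}|{model}", MODEL_LABELS[model], *genes]
                fh.write("\t".join(fields) + "\n")


def read_gene_sets_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file back as ``{set name: member genes}``."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
            out[fields[0]] = frozenset(f for f in fields[2:] if f)
    return out
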