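"""Protein–protein-interaction graph and bounded gene-level expansion.

SIF (Simple Interaction Format) files list one typed, directed edge per
line: ``source<TAB>interaction-type<TAB>target``.  Twelve interaction
types are recognised (the Pathway Commons binary-SIF vocabulary).  When
no drug directly targets a queried gene, the search "regresses" up the
network: drugs that hit the gene's upstream regulators or its partners
in a complex may antagonise the gene's activity too, which is the basis
for the repurposing suggestions this package emits.

Which labels count as "upstream or complex partner" is centralised in
``UPSTREAM_IN_TYPES`` / ``UPSTREAM_OUT_TYPES`` / ``COMPLEX_TYPE`` so the
policy can be revised in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .catalog import DrugCatalog, DrugRecord, drugs_targeting

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_TYPES",
    "UPSTREAM_IN_TYPES",
    "UPSTREAM_OUT_TYPES",
    "COMPLEX_TYPE",
    "InteractionEdge",
    "InteractionGraph",
    "ExpansionResult",
    "parse_sif",
    "upstream_interactors",
    "expand_search",
]

#: The closed set of twelve recognised interaction labels.
INTERACTION_TYPES = frozenset(
    {
        "catalysis-precedes",
        "chemical-affects",
        "consumption-controlled-by",
        "controls-expression-of",
        "controls-phosphorylation-of",
        "controls-production-of",
        "controls-state-change-of",
        "controls-transport-of",
        "controls-transport-of-chemical",
        "in-complex-with",
        "reacts-with",
        "used-to-produce",
    }
)

#: An edge ``g --label--> gene`` with one of these labels makes g an
#: upstream regulator of gene.
UPSTREAM_IN_TYPES = frozenset(
    {
        "controls-expression-of",
        "controls-state-change-of",
        "controls-phosphorylation-of",
        "controls-transport-of",
        "controls-production-of",
        "chemical-affects",
        "catalysis-precedes",
    }
)

#: Reversed semantics: ``gene --consumption-controlled-by--> g`` means g
#: controls the consumption of gene's product, so g is upstream.
UPSTREAM_OUT_TYPES = frozenset({"consumption-controlled-by"})

#: Complex membership is undirected: either orientation links partners.
COMPLEX_TYPE = "in-complex-with"


@dataclass(frozen=True)
class InteractionEdge:
    """One typed, directed interaction between two gene symbols."""

    source: str
    interaction_type: str
    target: str

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type: {self.interaction_type!r}")
        object.__setattr__(self, "source", self.source.upper())
        object.__setattr__(self, "target", self.target.upper())


class InteractionGraph:
    """Merged, deduplicated edge set backed by a networkx multidigraph."""

    def __init__(self) -> None:
        self._nx = nx.MultiDiGraph()
        self._edges: set[InteractionEdge] = set()
        #: Per-edge tag of the first file that contributed it.
        self.provenance: dict[InteractionEdge, str] = {}

    @property
    def edges(self) -> frozenset[InteractionEdge]:
        return frozenset(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, edge: object) -> bool:
        return edge in self._edges

    def add_edge(self, edge: InteractionEdge, provenance: str = "") -> bool:
        """Add *edge* unless already present; return whether it was new."""
        if edge in self._edges:
            return False
        self._edges.add(edge)
        self.provenance[edge] = provenance
        self._nx.add_edge(edge.source, edge.target, key=edge.interaction_type)
        return True

    def in_edges(self, gene: str) -> Iterable[tuple[str, str]]:
        """(source, type) pairs of edges pointing at *gene*."""
        g = gene.upper()
        if g not in self._nx:
            return []
        return [(u, k) for u, _, k in self._nx.in_edges(g, keys=True)]

    def out_edges(self, gene: str) -> Iterable[tuple[str, str]]:
        """(target, type) pairs of edges leaving *gene*."""
        g = gene.upper()
        if g not in self._nx:
            return []
        return [(v, k) for _, v, k in self._nx.out_edges(g, keys=True)]


def parse_sif(files: Sequence[str | Path] | str | Path) -> InteractionGraph:
    """Parse and merge one or more 3-column SIF files.

    Lines whose label is outside the twelve-type set, or which do not
    have exactly three tab-separated columns, are skipped with a warning.
    Duplicate (source, type, target) triples across files collapse to one
    edge.

    Raises
    ------
    ValueError
        If no parseable edge is found across all files.
    """
    if isinstance(files, (str, Path)):
        files = [files]
    graph = InteractionGraph()
    skipped = 0
    for file in files:
        path = Path(file)
        if not path.is_file():
            raise FileNotFoundError(f"SIF file not found: {path}")
        for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                skipped += 1
                logger.warning("%s:%d: skipping malformed SIF line: %r", path, lineno, raw)
                continue
            source, itype, target = (p.strip() for p in parts)
            if itype not in INTERACTION_TYPES:
                skipped += 1
                logger.warning(
                    "%s:%d: skipping unknown interaction type %r", path, lineno, itype
                )
                continue
            graph.add_edge(
                InteractionEdge(source, itype, target), provenance=path.name
            )
    if len(graph) == 0:
        raise ValueError("no parseable interaction edges found in input SIF file(s)")
    if skipped:
        logger.warning("skipped %d unusable SIF line(s)", skipped)
    return graph


def upstream_interactors(gene: str, graph: InteractionGraph) -> set[str]:
    """Genes upstream of *gene*: its regulators and complex partners.

    A gene g qualifies when (a) an edge ``g -> gene`` carries a control
    label, (b) ``gene -> g`` carries a reversed-semantics label, or
    (c) an ``in-complex-with`` edge links g and gene in either direction.
    Downstream regulatory edges (``gene -> g`` with a control label) do
    not qualify.  The queried gene is never its own interactor.
    """
    g = gene.upper()
    found: set[str] = set()
    for source, itype in graph.in_edges(g):
        if itype in UPSTREAM_IN_TYPES or itype == COMPLEX_TYPE:
            found.add(source)
    for target, itype in graph.out_edges(g):
        if itype in UPSTREAM_OUT_TYPES or itype == COMPLEX_TYPE:
            found.add(target)
    found.discard(g)
    return found


@dataclass
class ExpansionResult:
    """Per-level record of a bounded upstream drug search.

    ``levels[0]`` always maps the queried gene to its direct drug hits;
    ``levels[k]`` (k >= 1) maps each gene first reached at distance k to
    the eligible cancer drugs that target it directly.  A gene appears at
    exactly one level.
    """

    gene: str
    levels: dict[int, dict[str, list[DrugRecord]]] = field(default_factory=dict)
    visited: set[str] = field(default_factory=set)

    def drugs_at(self, level: int) -> list[DrugRecord]:
        """Unique drugs first reported at *level*, sorted by accession."""
        seen: dict[str, DrugRecord] = {}
        for records in self.levels.get(level, {}).values():
            for r in records:
                seen.setdefault(r.drug_id, r)
        return [seen[i] for i in sorted(seen)]

    def all_drugs(self) -> list[DrugRecord]:
        """Flattened view: unique drugs across all levels, sorted by accession."""
        seen: dict[str, DrugRecord] = {}
        for level in sorted(self.levels):
            for records in self.levels[level].values():
                for r in records:
                    seen.setdefault(r.drug_id, r)
        return [seen[i] for i in sorted(seen)]

    def interactors_of(self, drug_id: str) -> list[str]:
        """Genes (levels >= 1) through which *drug_id* was reached, sorted."""
        genes = {
            g
            for level, per_gene in self.levels.items()
            if level >= 1
            for g, records in per_gene.items()
            if any(r.drug_id == drug_id for r in records)
        }
        return sorted(genes)


def expand_search(
    gene: str,
    max_level: int,
    graph: InteractionGraph,
    catalog: DrugCatalog,
) -> ExpansionResult:
    """Breadth-first upstream drug search bounded by *max_level*.

    If the queried gene has direct drug hits, only level 0 is populated
    and no expansion occurs.  Otherwise the frontier grows one level of
    upstream interactors at a time (lexicographic order within a level),
    recording each interactor's direct drug hits; hits accumulate at
    every level up to *max_level*.  Visited genes are never re-expanded,
    so expansion work is bounded by ``|edges| * max_level``.
    """
    if max_level < 0:
        raise ValueError("max_level must be non-negative")
    g = gene.strip().upper()
    result = ExpansionResult(gene=g, visited={g})
    direct = drugs_targeting(g, catalog)
    result.levels[0] = {g: direct}
    if direct or max_level == 0:
        return result
    frontier = [g]
    for level in range(1, max_level + 1):
        next_genes: set[str] = set()
        for node in frontier:
            next_genes |= upstream_interactors(node, graph)
        next_genes -= result.visited
        if not next_genes:
            break
        ordered = sorted(next_genes)
        result.levels[level] = {n: drugs_targeting(n, catalog) for n in ordered}
        result.visited |= next_genes
        frontier = ordered
    return result
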