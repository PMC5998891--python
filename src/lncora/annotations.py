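"""Readers for genomic annotations (GTF), ontology structure (OBO) and
term-to-gene maps (GAF 2.x / two-column TSV), plus the shared feature model.

Coordinates are kept in the GTF convention (1-based, inclusive) end to end;
all downstream distance arithmetic assumes it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from lncora.errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}
_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GenomicFeature:
    """One gene-level feature: a protein-coding gene or a lncRNA.

    Coordinates are 1-based and inclusive, as in GTF.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.feature_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.feature_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"{self.feature_id}: invalid strand {self.strand!r}")
        if self.biotype not in {"protein_coding", "lncRNA"}:
            raise ValueError(f"{self.feature_id}: invalid biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def parse_gtf(path, biotype: str = "protein_coding") -> list[GenomicFeature]:
    """Parse a 9-column GTF into gene-level features.

    Transcript/exon records sharing a ``gene_id`` are collapsed to one
    feature spanning min(start)..max(end). Comment lines (``#``) and blank
    lines are skipped. Raises :class:`ParseError` with the offending line
    number on malformed input.
    """
    spans: dict[str, dict] = {}
    order: list[str] = []
    n_records = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, _feat, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if end < start:
                raise ParseError(f"{path}: line {lineno}: end ({end}) < start ({start})")
            if start < 1:
                raise ParseError(f"{path}: line {lineno}: start ({start}) < 1")
            attr_map = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            n_records += 1
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand if strand in _VALID_STRANDS else ".",
                    "name": attr_map.get("gene_name"),
                }
                order.append(gene_id)
            else:
                if rec["chrom"] != chrom:
                    raise ParseError(
                        f"{path}: line {lineno}: gene {gene_id} spans multiple "
                        f"chromosomes ({rec['chrom']} vs {chrom})"
                    )
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
                if rec["name"] is None:
                    rec["name"] = attr_map.get("gene_name")
    features = [
        GenomicFeature(
            feature_id=gid,
            chrom=spans[gid]["chrom"],
            start=spans[gid]["start"],
            end=spans[gid]["end"],
            strand=spans[gid]["strand"],
            biotype=biotype,
            name=spans[gid]["name"],
        )
        for gid in order
    ]
    logger.info(
        "parse_gtf(%s): %d records collapsed to %d gene-level features",
        path, n_records, len(features),
    )
    return features


def write_gtf(features: Iterable[GenomicFeature], path) -> None:
    """Write gene-level features as one GTF line each (feature type 'gene')."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}";'
            if f.name:
                attrs += f' gene_name "{f.name}";'
            fh.write(
                f"{f.chrom}\tlncora\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


@dataclass
class TermMap:
    """Term-to-gene annotation map (GO, KEGG, or custom namespace)."""

    terms: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespace: str = "custom"

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms


def parse_term_map(path, format: str = "tsv", namespace: str = "custom") -> TermMap:
    """Read a term-to-gene map from a two-column TSV or a GAF 2.x file.

    TSV rows are ``term_id <TAB> gene_id``; duplicates collapse. GAF rows
    with a NOT qualifier are excluded per the GAF spec. Rows with missing
    fields are skipped and counted in the log.
    """
    if format not in {"tsv", "gaf"}:
        raise ConfigError(f"unknown term map format: {format!r}")
    terms: dict[str, set[str]] = {}
    n_rows = n_skipped = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "tsv":
                if len(cols) < 2 or not cols[0] or not cols[1]:
                    n_skipped += 1
                    continue
                term, gene = cols[0], cols[1]
            else:  # GAF 2.x: DB, DB_Object_ID, Symbol, Qualifier, GO_ID, ...
                if len(cols) < 5 or not cols[1] or not cols[4]:
                    n_skipped += 1
                    continue
                qualifier = cols[3]
                if "NOT" in qualifier.split("|"):
                    n_skipped += 1
                    continue
                term, gene = cols[4], cols[1]
            terms.setdefault(term, set()).add(gene)
            n_rows += 1
    if not terms:
        raise ParseError(f"{path}: no term-to-gene rows found")
    logger.info(
        "parse_term_map(%s, %s): %d rows into %d terms (%d skipped)",
        path, format, n_rows, len(terms), n_skipped,
    )
    return TermMap(
        terms={t: frozenset(g) for t, g in terms.items()}, namespace=namespace
    )


class OntologyDag:
    """Directed acyclic graph of ontology terms.

    Edges run child -> parent with a ``relation`` attribute (``is_a`` or
    ``part_of``). Roots are terms with no parents.
    """

    def __init__(self, graph: nx.DiGraph, labels: Mapping[str, str] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ParseError(f"ontology graph contains a cycle: {cycle}")
        self._graph = graph
        self.labels = dict(labels or {})

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self._graph.nodes if self._graph.out_degree(n) == 0}

    def parents(self, term: str) -> set[str]:
        """Direct parents of ``term``."""
        return set(self._graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All proper ancestors of ``term`` (transitive, excluding itself)."""
        return nx.descendants(self._graph, term)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()


def parse_obo(path, include_part_of: bool = False) -> OntologyDag:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDag`.

    Obsolete terms are dropped (count logged). Edges come from ``is_a``
    lines and, when ``include_part_of`` is set, ``relationship: part_of``
    lines. A cyclic graph raises :class:`ParseError` naming one cycle.
    """
    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    n_obsolete = 0
    term_id: str | None = None
    term_name: str | None = None
    obsolete = False
    edges: list[tuple[str, str, str]] = []
    in_term = False

    def flush() -> None:
        nonlocal n_obsolete
        if term_id is None:
            return
        if obsolete:
            n_obsolete += 1
            return
        graph.add_node(term_id)
        if term_name:
            labels[term_id] = term_name

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush()
                term_id, term_name, obsolete = None, None, False
                in_term = True
                continue
            if line.startswith("["):  # [Typedef] etc.
                flush()
                term_id = None
                in_term = False
                continue
            if not in_term or not line:
                continue
            if line.startswith("id:"):
                term_id = line[3:].strip()
            elif line.startswith("name:"):
                term_name = line[5:].strip()
            elif line.startswith("is_obsolete:"):
                obsolete = line.split(":", 1)[1].strip() == "true"
            elif line.startswith("is_a:") and term_id:
                parent = line[5:].split("!")[0].strip()
                edges.append((term_id, parent, "is_a"))
            elif line.startswith("relationship:") and term_id:
                parts = line.split(":", 1)[1].split("!")[0].split()
                if len(parts) >= 2 and parts[0] == "part_of" and include_part_of:
                    edges.append((term_id, parts[1], "part_of"))
    flush()

    kept = set(graph.nodes)
    for child, parent, rel in edges:
        if child in kept and parent in kept:
            graph.add_edge(child, parent, relation=rel)
    logger.info(
        "parse_obo(%s): %d terms, %d edges (%d obsolete dropped)",
        path, graph.number_of_nodes(), graph.number_of_edges(), n_obsolete,
    )
    return OntologyDag(graph, labels)
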