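"""KEGG KGML pathway parsing and gene-pair extraction.

A KGML file describes one pathway as ``entry`` elements (genes, compounds,
groups of entries) and ``relation`` elements connecting two entries with a
type (PPrel protein-protein, GErel gene expression, ECrel enzyme-enzyme,
PCrel protein-compound, maplink). Here each relation is expanded to the
cartesian product of the gene sets of its two endpoints, preserving the
entry1 -> entry2 direction, which downstream fixes the regression axis
(gene_a on x, gene_b on y).

Files are parsed offline; no KEGG REST calls are made.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from lxml import etree

from .errors import FormatError
from .expression_io import ProbeAnnotation

logger = logging.getLogger(__name__)

KNOWN_RELATION_TYPES = frozenset(
    {"PPrel", "GErel", "ECrel", "PCrel", "maplink"}
)
#: transcription-factor/target and protein-protein links; the pair kinds
#: relevant to expression-correlation analysis
DEFAULT_RELATION_TYPES = frozenset({"PPrel", "GErel"})


@dataclass
class PathwayGraph:
    """Parsed KGML pathway: gene entries and typed directed relations."""

    pathway_id: str
    name: str
    entries: dict[str, frozenset[str]]  # entry_id -> gene ids (groups expanded)
    relations: list[tuple[str, str, str]]  # (entry1_id, entry2_id, type)


@dataclass(frozen=True)
class GenePair:
    """Directed interacting gene pair aggregated over pathways."""

    gene_a: str
    gene_b: str
    pathway_ids: frozenset[str] = field(default_factory=frozenset)
    relation_types: frozenset[str] = field(default_factory=frozenset)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def parse_kgml(source) -> PathwayGraph:
    """Parse KGML XML (string, bytes or path) into a PathwayGraph.

    Gene-type entries keep every gene id listed in their ``name`` attribute;
    group entries expand to the union of their components' genes. Relations
    referencing unknown entries are skipped with a warning.
    """
    try:
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            tree = etree.parse(str(source))
            root = tree.getroot()
        else:
            if isinstance(source, str):
                source = source.encode()
            root = etree.fromstring(source)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed KGML: {exc}") from exc
    if root.tag != "pathway":
        raise FormatError(f"expected <pathway> root, got <{root.tag}>")

    pathway_id = root.get("name", "").removeprefix("path:")
    title = root.get("title", "")

    gene_entries: dict[str, frozenset[str]] = {}
    group_components: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        entry_id = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            genes = frozenset(entry.get("name", "").split())
            if not genes:
                logger.warning(
                    "%s: gene entry %s has no gene ids", pathway_id, entry_id
                )
                continue
            gene_entries[entry_id] = genes
        elif etype == "group":
            group_components[entry_id] = [
                comp.get("id") for comp in entry.findall("component")
            ]

    entries = dict(gene_entries)
    for entry_id, components in group_components.items():
        genes: set[str] = set()
        for comp_id in components:
            genes |= entries.get(comp_id, frozenset())
        if genes:
            entries[entry_id] = frozenset(genes)

    relations: list[tuple[str, str, str]] = []
    for relation in root.findall("relation"):
        e1, e2 = relation.get("entry1"), relation.get("entry2")
        rtype = relation.get("type", "")
        if e1 not in entries or e2 not in entries:
            logger.warning(
                "%s: skipping relation %s->%s (%s): unknown or non-gene entry",
                pathway_id, e1, e2, rtype,
            )
            continue
        relations.append((e1, e2, rtype))

    return PathwayGraph(pathway_id, title, entries, relations)


def extract_gene_pairs(
    graph: PathwayGraph,
    relation_types: frozenset[str] = DEFAULT_RELATION_TYPES,
) -> list[GenePair]:
    """Expand relations into directed gene pairs.

    Each relation contributes genes(entry1) x genes(entry2); self-pairs are
    removed; duplicate pairs are merged with the union of relation types.
    Output order is deterministic (sorted by gene pair) and independent of
    entry order in the XML.
    """
    unknown = set(relation_types) - KNOWN_RELATION_TYPES
    if unknown:
        raise ValueError(f"unknown relation types: {sorted(unknown)}")
    merged: dict[tuple[str, str], set[str]] = {}
    for e1, e2, rtype in graph.relations:
        if rtype not in relation_types:
            continue
        for gene_a in graph.entries[e1]:
            for gene_b in graph.entries[e2]:
                if gene_a == gene_b:
                    continue
                merged.setdefault((gene_a, gene_b), set()).add(rtype)
    return [
        GenePair(a, b, frozenset({graph.pathway_id}), frozenset(types))
        for (a, b), types in sorted(merged.items())
    ]


def merge_pairs(pair_lists: list[list[GenePair]]) -> list[GenePair]:
    """Merge gene pairs across pathways, unioning pathway ids and types."""
    merged: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for pairs in pair_lists:
        for pair in pairs:
            paths, types = merged.setdefault(pair.key, (set(), set()))
            paths |= pair.pathway_ids
            types |= pair.relation_types
    return [
        GenePair(a, b, frozenset(paths), frozenset(types))
        for (a, b), (paths, types) in sorted(merged.items())
    ]


def pairs_to_probes(
    pairs: list[GenePair], annotation: ProbeAnnotation
) -> list[tuple[str, str, GenePair]]:
    """Cross each gene pair's probes: every probe of gene_a with every probe
    of gene_b. Pairs with an unannotated gene are dropped with a warning;
    probe self-pairs are removed."""
    out: list[tuple[str, str, GenePair]] = []
    n_unmapped = 0
    for pair in pairs:
        probes_a = annotation.probes_for(pair.gene_a)
        probes_b = annotation.probes_for(pair.gene_b)
        if not probes_a or not probes_b:
            n_unmapped += 1
            logger.warning(
                "no probes for gene pair %s -> %s", pair.gene_a, pair.gene_b
            )
            continue
        for pa in probes_a:
            for pb in probes_b:
                if pa != pb:
                    out.append((pa, pb, pair))
    if n_unmapped:
        logger.info("%d gene pairs dropped (unannotated gene)", n_unmapped)
    return out


def load_pathway_dir(path) -> list[PathwayGraph]:
    """Parse every ``*.xml`` / ``*.kgml`` file in a directory, sorted by name."""
    names = sorted(
        f for f in os.listdir(path) if f.endswith((".xml", ".kgml"))
    )
    if not names:
        raise FormatError(f"no KGML files (*.xml, *.kgml) in {path}")
    return [parse_kgml(os.path.join(path, f)) for f in names]


def write_edge_list(pairs: list[GenePair], path) -> None:
    """Export pairs as TSV: pathway_id, gene_a, gene_b, relation_types."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("pathway_id\tgene_a\tgene_b\trelation_types\n")
        for pair in pairs:
            for pathway_id in sorted(pair.pathway_ids):
                out.write(
                    f"{pathway_id}\t{pair.gene_a}\t{pair.gene_b}\t"
                    f"{','.join(sorted(pair.relation_types))}\n"
                )
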