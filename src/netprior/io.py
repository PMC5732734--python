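"""Readers and writers for the file formats the tool touches.

Edge lists come in three dialects: a generic 2-3 column TSV
(``geneA geneB [score]``), Cytoscape SIF (``node relation node [node ...]``),
and the STRING ``protein.links`` dialect (space separated, with a
``combined_score`` column scaled 0-1000).  Annotations come either as a
plain two-column gene/term TSV or as GAF 2.x, optionally closed over the
``is_a`` ancestors of an OBO ontology.  Gene identifiers are treated as
case-sensitive strings; the only canonicalization applied is whitespace
stripping (no alias resolution).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: default "high confidence" cut on STRING combined scores (0-1000 scale)
STRING_DEFAULT_MIN_SCORE = 700.0


class EdgeRecord(NamedTuple):
    """One undirected interaction with an optional source confidence."""

    gene_a: str
    gene_b: str
    score: Optional[float] = None


class EdgeList(list):
    """A list of :class:`EdgeRecord` that remembers how many self-loops
    were skipped during parsing."""

    def __init__(self, records: Iterable[EdgeRecord] = (), n_self_loops: int = 0):
        super().__init__(records)
        self.n_self_loops = n_self_loops


@dataclass
class AnnotationMap:
    """Gene -> set of ontology term identifiers.

    Genes absent from :attr:`gene_terms` are representable: :meth:`terms`
    returns an empty set for them rather than raising.
    """

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_aspect: dict[str, str] = field(default_factory=dict)

    def terms(self, gene: str) -> set[str]:
        return self.gene_terms.get(gene, set())

    def genes(self) -> set[str]:
        return set(self.gene_terms)

    def add(self, gene: str, term: str) -> None:
        self.gene_terms.setdefault(gene, set()).add(term)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _parse_tsv_line(parts: list[str]) -> tuple[str, str, Optional[float]]:
    a, b = parts[0], parts[1]
    score = float(parts[2]) if len(parts) >= 3 else None
    return a, b, score


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    min_score: Optional[float] = None,
) -> EdgeList:
    """Read an undirected edge list.

    Duplicate (a, b)/(b, a) pairs are merged keeping the maximum score;
    self-loops are skipped and counted on the returned
    :class:`EdgeList.n_self_loops`.  When ``min_score`` is given, only
    edges with ``score >= min_score`` survive.  For the ``string-links``
    dialect a missing ``min_score`` defaults to 700 (the conventional
    high-confidence cut).

    Raises
    ------
    ValueError
        on an unparseable line (the message names the 1-based line
        number) or an unknown dialect.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif", "string-links"):
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    if dialect == "string-links" and min_score is None:
        min_score = STRING_DEFAULT_MIN_SCORE

    merged: dict[tuple[str, str], Optional[float]] = {}
    n_self = 0
    score_col: Optional[int] = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if dialect == "string-links" and score_col is None:
                # first non-comment row must be the header
                if "combined_score" not in parts:
                    raise ValueError(
                        f"{path}:{lineno}: string-links header lacks a "
                        "combined_score column"
                    )
                score_col = parts.index("combined_score")
                continue
            try:
                pairs = _extract_pairs(parts, dialect, score_col)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line: {line!r}") from exc
            for a, b, score in pairs:
                a, b = a.strip(), b.strip()
                if not a or not b:
                    raise ValueError(f"{path}:{lineno}: empty gene symbol")
                if a == b:
                    n_self += 1
                    continue
                key = _edge_key(a, b)
                prev = merged.get(key, ...)
                if prev is ...:
                    merged[key] = score
                elif score is not None and (prev is None or score > prev):
                    merged[key] = score

    if n_self:
        logger.warning("skipped %d self-loop(s) in %s", n_self, path)

    records = []
    for (a, b), score in merged.items():
        if min_score is not None and (score is None or score < min_score):
            continue
        records.append(EdgeRecord(a, b, score))
    return EdgeList(records, n_self_loops=n_self)


def _extract_pairs(
    parts: list[str], dialect: str, score_col: Optional[int]
) -> list[tuple[str, str, Optional[float]]]:
    if dialect == "tsv":
        if len(parts) < 2:
            raise ValueError("need at least two columns")
        return [_parse_tsv_line(parts)]
    if dialect == "sif":
        if len(parts) == 1:
            return []  # isolated node line: no edges
        if len(parts) < 3:
            raise ValueError("SIF needs 'node relation node [node ...]'")
        src = parts[0]
        return [(src, tgt, None) for tgt in parts[2:]]
    # string-links
    if len(parts) <= score_col:
        raise ValueError("row shorter than combined_score column")
    return [(parts[0], parts[1], float(parts[score_col]))]


def read_seed_list(path: str | Path) -> list[str]:
    """Read a seed (disease) gene list: one symbol per line.

    Returns an ordered, duplicate-free list; raises on an empty file.
    """
    seeds: list[str] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for raw in fh:
            sym = raw.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym not in seen:
                seen.add(sym)
                seeds.append(sym)
    if not seeds:
        raise ValueError(f"seed list {path} is empty")
    return seeds


def _isa_ancestors(onto: "nx.MultiDiGraph", term: str) -> set[str]:
    """All ancestors of ``term`` reachable through is_a edges only."""
    out: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t not in onto:
            continue
        for _, parent, rel in onto.out_edges(t, keys=True):
            if rel == "is_a" and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def read_annotations(
    gaf_or_tsv_path: str | Path,
    obo_path: Optional[str | Path] = None,
    ancestor_closure: bool = True,
) -> AnnotationMap:
    """Read gene -> term annotations from GAF 2.x or a two-column TSV.

    The GAF dialect is detected by a ``!gaf-version`` header.  When an
    OBO ontology is supplied and ``ancestor_closure`` is true, each
    gene's term set is closed over is_a ancestors (part_of and other
    relations are not followed).  Terms absent from the ontology are
    kept without closure, with a logged warning.
    """
    path = Path(gaf_or_tsv_path)
    ann = AnnotationMap()
    with path.open() as fh:
        first = fh.readline()
        is_gaf = first.lstrip().lower().startswith("!gaf")
        fh.seek(0)
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            if is_gaf:
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ValueError(f"{path}:{lineno}: truncated GAF row")
                gene, term, aspect = cols[2].strip(), cols[4].strip(), cols[8].strip()
                if aspect:
                    ann.term_aspect[term] = aspect
            else:
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 2:
                    raise ValueError(f"{path}:{lineno}: need gene and term columns")
                gene, term = cols[0].strip(), cols[1].strip()
            if not gene or not term:
                raise ValueError(f"{path}:{lineno}: empty gene or term")
            ann.add(gene, term)
    if not ann.gene_terms:
        raise ValueError(f"annotation file {path} contains no associations")

    if obo_path is not None and ancestor_closure:
        import obonet

        onto = obonet.read_obo(str(obo_path))
        missing: set[str] = set()
        closure_cache: dict[str, set[str]] = {}
        for gene, terms in ann.gene_terms.items():
            closed = set(terms)
            for t in terms:
                if t not in onto:
                    missing.add(t)
                    continue
                if t not in closure_cache:
                    closure_cache[t] = _isa_ancestors(onto, t)
                closed |= closure_cache[t]
            ann.gene_terms[gene] = closed
        if missing:
            logger.warning(
                "%d annotated term(s) absent from the ontology; kept without "
                "closure: %s", len(missing), ", ".join(sorted(missing)[:5]),
            )
    return ann


# ---------------------------------------------------------------------------
# ranked-score tables


def write_ranking(ranking: Sequence, path: str | Path, config_hash: str | None = None) -> None:
    """Write a ranked gene table as TSV (rank, gene, score, is_seed).

    Scores are printed with 12 significant digits, which is the
    round-trip precision contract of :func:`read_ranking`.
    """
    if not ranking:
        raise ValueError("refusing to write an empty ranking")
    with Path(path).open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write("rank\tgene\tscore\tis_seed\n")
        for row in ranking:
            fh.write(f"{row.rank}\t{row.gene}\t{row.score:.12g}\t{int(row.is_seed)}\n")


def read_ranking(path: str | Path) -> list:
    from .propagation import RankedGene  # local import: avoid cycle

    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("rank\t") or not line.strip():
                continue
            rank, gene, score, is_seed = line.rstrip("\n").split("\t")
            rows.append(RankedGene(gene, float(score), int(rank), bool(int(is_seed))))
    if not rows:
        raise ValueError(f"ranking file {path} is empty")
    return rows


# ---------------------------------------------------------------------------
# network JSON serialization (the `netprior build`/`weight` interchange format)


def write_network_json(net, path: str | Path) -> None:
    """Serialize a weighted network as documented JSON."""
    payload = {
        "nodes": [
            {
                "id": n,
                "weight": net.graph.nodes[n]["weight"],
                "is_seed": bool(net.graph.nodes[n]["is_seed"]),
            }
            for n in net.nodes
        ],
        "edges": [
            {"a": a, "b": b, "weight": d["weight"]}
            for a, b, d in sorted(
                net.graph.edges(data=True), key=lambda e: _edge_key(e[0], e[1])
            )
        ],
        "missing_seeds": list(net.missing_seeds),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_network_json(path: str | Path):
    from .network import WeightedNetwork  # local import: avoid cycle

    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for nd in payload["nodes"]:
        g.add_node(nd["id"], weight=float(nd["weight"]), is_seed=bool(nd["is_seed"]))
    for ed in payload["edges"]:
        g.add_edge(ed["a"], ed["b"], weight=float(ed["weight"]))
    return WeightedNetwork(graph=g, missing_seeds=tuple(payload.get("missing_seeds", ())))
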