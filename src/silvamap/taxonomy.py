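"""NCBI taxonomy dump parsing, name lookup and tree queries.

This module handles the two flat files shipped in NCBI's ``taxdmp``
archive:

* ``names.dmp`` — one taxon name per line, in several *name classes*
  (scientific name, synonym, equivalent name, misspelling, ...).  All
  classes are indexed, which raises the chance that a free-text organism
  name from a reference database resolves to a taxon ID.
* ``nodes.dmp`` — the tree itself: each taxon's parent link and rank.

Both files use the taxdump dialect: fields separated by ``\\t|\\t`` and a
trailing ``\\t|`` terminator on every line.

On top of the parsed data the module provides :class:`NameIndex` (a
normalized-name hash map used by the mapping algorithm) and
:class:`TaxonomyTree` with ancestry, rank and lowest-common-ancestor
queries used by the read binning step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "NameClass",
    "TaxonRecord",
    "TaxonomyTree",
    "NameIndex",
    "parse_names_dump",
    "parse_nodes_dump",
    "build_name_index",
    "lca",
]


class ParseError(ValueError):
    """A malformed line in an input file; carries file path and line number."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{self.line_no}: {message}")


class NameClass(str, Enum):
    """Name classes found in names.dmp; unknown classes collapse to OTHER."""

    SCIENTIFIC = "scientific name"
    SYNONYM = "synonym"
    EQUIVALENT = "equivalent name"
    MISSPELLING = "misspelling"
    OTHER = "other"

    @classmethod
    def from_dump(cls, text: str) -> "NameClass":
        try:
            return cls(text.strip())
        except ValueError:
            return cls.OTHER


@dataclass(frozen=True)
class TaxonRecord:
    """One line of names.dmp: a (taxon id, name, name class) triple."""

    taxon_id: int
    name: str
    name_class: NameClass = NameClass.SCIENTIFIC

    def __post_init__(self) -> None:
        if self.taxon_id <= 0:
            raise ValueError(f"taxon_id must be positive, got {self.taxon_id}")
        stripped = self.name.strip()
        if not stripped:
            raise ValueError("taxon name must be non-empty")
        object.__setattr__(self, "name", stripped)


def _split_dump_line(line: str) -> list[str]:
    """Split one taxdump line into fields.

    Fields are separated by ``\\t|\\t``; the line is terminated by ``\\t|``
    (with or without trailing whitespace/newline).
    """
    line = line.rstrip("\r\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_names_dump(path: str | Path) -> list[TaxonRecord]:
    """Parse a names.dmp-dialect file into taxon name records.

    The 4th field (name class) is taken verbatim and mapped onto
    :class:`NameClass`; classes the enum does not know become ``OTHER``.

    Raises :class:`ParseError` (with line number) on a malformed line.
    """
    records: list[TaxonRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            if len(fields) < 4:
                raise ParseError(path, line_no, f"expected >=4 fields, got {len(fields)}")
            try:
                taxon_id = int(fields[0].strip())
            except ValueError:
                raise ParseError(path, line_no, f"non-integer taxon id {fields[0]!r}") from None
            name = fields[1].strip()
            if not name:
                raise ParseError(path, line_no, "empty taxon name")
            try:
                record = TaxonRecord(taxon_id, name, NameClass.from_dump(fields[3]))
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
            records.append(record)
    return records


class TaxonomyTree:
    """A rooted taxonomy: parent links and ranks keyed by taxon id.

    The root is the unique node whose parent is itself (taxon 1 in the
    real NCBI dump).  Construction validates that every parent exists,
    that exactly one root is present and that every node reaches the
    root (no cycles).
    """

    def __init__(self, nodes: Mapping[int, tuple[int, str]]):
        if not nodes:
            raise ValueError("taxonomy tree needs at least one node")
        self.nodes: dict[int, tuple[int, str]] = dict(nodes)

        orphans = sorted(
            {parent for parent, _ in self.nodes.values()} - set(self.nodes)
        )
        if orphans:
            raise ValueError(f"parent ids absent from node table: {orphans}")

        roots = [tid for tid, (parent, _) in self.nodes.items() if parent == tid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one self-parented root, found {roots}")
        self.root_id: int = roots[0]

        self._depth: dict[int, int] = {self.root_id: 0}
        for tid in self.nodes:
            self._resolve_depth(tid)

        self._children: dict[int, list[int]] | None = None

    def _resolve_depth(self, taxon_id: int) -> int:
        path: list[int] = []
        tid = taxon_id
        while tid not in self._depth:
            path.append(tid)
            tid = self.nodes[tid][0]
            if tid in path:
                raise ValueError(f"cycle in taxonomy involving taxon {tid}")
        depth = self._depth[tid]
        for node in reversed(path):
            depth += 1
            self._depth[node] = depth
        return self._depth[taxon_id]

    # -- basic queries ------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self.nodes)

    def parent(self, taxon_id: int) -> int:
        self._require(taxon_id)
        return self.nodes[taxon_id][0]

    def rank(self, taxon_id: int) -> str:
        self._require(taxon_id)
        return self.nodes[taxon_id][1]

    @property
    def ranks(self) -> set[str]:
        return {rank for _, rank in self.nodes.values()}

    def depth(self, taxon_id: int) -> int:
        self._require(taxon_id)
        return self._depth[taxon_id]

    def ancestors(self, taxon_id: int) -> list[int]:
        """Path from the node itself up to the root (self first)."""
        self._require(taxon_id)
        path = [taxon_id]
        tid = taxon_id
        while tid != self.root_id:
            tid = self.nodes[tid][0]
            path.append(tid)
        return path

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        """True iff *ancestor* lies on descendant's root path (or is it)."""
        return ancestor in self.ancestors(descendant)

    def children(self) -> dict[int, list[int]]:
        """Child lists keyed by parent id, each sorted by taxon id."""
        if self._children is None:
            table: dict[int, list[int]] = {tid: [] for tid in self.nodes}
            for tid, (parent, _) in self.nodes.items():
                if tid != parent:
                    table[parent].append(tid)
            for kids in table.values():
                kids.sort()
            self._children = table
        return self._children

    def _require(self, taxon_id: int) -> None:
        if taxon_id not in self.nodes:
            raise KeyError(f"taxon {taxon_id} not in taxonomy")

    # -- LCA ----------------------------------------------------------

    def lca(self, taxon_ids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxa.

        Returns the deepest node that is an ancestor-or-self of every
        input id.  Order-independent; ``lca({x}) == x``.
        """
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of an empty set is undefined")
        # Root-first paths; the LCA is the last element of their common prefix.
        paths = [list(reversed(self.ancestors(tid))) for tid in ids]
        shortest = min(len(p) for p in paths)
        result = self.root_id
        for level in range(shortest):
            node = paths[0][level]
            if all(p[level] == node for p in paths[1:]):
                result = node
            else:
                break
        return result


def lca(tree: TaxonomyTree, taxon_ids: Iterable[int]) -> int:
    """Module-level convenience wrapper for :meth:`TaxonomyTree.lca`."""
    return tree.lca(taxon_ids)


def parse_nodes_dump(path: str | Path) -> TaxonomyTree:
    """Parse a nodes.dmp-dialect file into a validated :class:`TaxonomyTree`.

    Field 1 is the taxon id, field 2 its parent, field 3 the rank.
    Extra fields (the real dump has 13) are ignored.
    """
    nodes: dict[int, tuple[int, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            if len(fields) < 3:
                raise ParseError(path, line_no, f"expected >=3 fields, got {len(fields)}")
            try:
                taxon_id = int(fields[0].strip())
                parent_id = int(fields[1].strip())
            except ValueError:
                raise ParseError(path, line_no, "non-integer taxon/parent id") from None
            nodes[taxon_id] = (parent_id, fields[2].strip())
    if not nodes:
        raise ParseError(path, 0, "empty nodes file")
    try:
        return TaxonomyTree(nodes)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


class NameIndex:
    """Hash map from normalized taxon names to (taxon id, name class) lists.

    Normalization strips outer whitespace and collapses internal runs to
    a single space; matching is otherwise case-sensitive (case-variant
    retries are the mapping algorithm's job, not the index's).

    Homonyms — one name bound to several taxa — keep all bindings;
    scientific-name entries are ordered before other classes so that
    :meth:`resolve` can prefer them.
    """

    def __init__(self, records: Iterable[TaxonRecord] = ()):
        self._entries: dict[str, list[tuple[int, NameClass]]] = {}
        for record in records:
            self.add(record)

    @staticmethod
    def normalize(name: str) -> str:
        return " ".join(name.split())

    def add(self, record: TaxonRecord) -> None:
        key = self.normalize(record.name)
        entries = self._entries.setdefault(key, [])
        pair = (record.taxon_id, record.name_class)
        if pair in entries:
            return
        if record.name_class is NameClass.SCIENTIFIC:
            insert_at = sum(
                1 for _, cls in entries if cls is NameClass.SCIENTIFIC
            )
            entries.insert(insert_at, pair)
        else:
            entries.append(pair)

    def lookup(self, name: str) -> list[tuple[int, NameClass]]:
        """All bindings for a name (scientific-class entries first)."""
        return list(self._entries.get(self.normalize(name), ()))

    def resolve(self, name: str) -> int | None:
        """Deterministic single-taxon resolution of a name.

        Prefers scientific-name bindings; among equally-preferred
        bindings the numerically smallest taxon id wins (with a logged
        warning, since that is a genuine homonym).
        """
        entries = self.lookup(name)
        if not entries:
            return None
        scientific = [tid for tid, cls in entries if cls is NameClass.SCIENTIFIC]
        pool = scientific if scientific else [tid for tid, _ in entries]
        if len(set(pool)) > 1:
            log.warning(
                "homonym %r resolves to taxa %s; choosing smallest id",
                name,
                sorted(set(pool)),
            )
        return min(pool)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return self.normalize(name) in self._entries

    @property
    def taxon_ids(self) -> set[int]:
        """Codomain: every taxon id reachable through the index."""
        return {tid for entries in self._entries.values() for tid, _ in entries}


def build_name_index(records: Sequence[TaxonRecord]) -> NameIndex:
    """Build the name hash map over every record's name, all classes."""
    return NameIndex(records)
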