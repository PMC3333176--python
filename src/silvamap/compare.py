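"""Side-by-side comparison of taxonomic profiles from several classifiers.

Profiles from this package's own binning and flat genus/abundance CSV
exports from external services are placed on the shared NCBI taxonomy
and emitted as a table with, per sample, a *raw* column (reads assigned
to exactly that node) and a *summarized* column (reads assigned to the
node or anywhere in its subtree).  Flat CSV sources put all their mass
directly on genus nodes; no hierarchy is inferred for them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import TaxonomicProfile
from .taxonomy import NameIndex, ParseError, TaxonomyTree

log = logging.getLogger(__name__)

__all__ = [
    "ComparisonTable",
    "import_csv_profile",
    "summarize",
    "build_comparison",
    "write_comparison",
]


def import_csv_profile(
    path: str | Path, index: NameIndex, sample_id: str | None = None
) -> TaxonomicProfile:
    """Import a headerless two-column (genus, abundance) CSV profile.

    Genus names are resolved through the name index with the standard
    homonym rule; unresolvable names accumulate in the profile's
    no-hits bin.  A non-integer abundance raises :class:`ParseError`
    with the line number.
    """
    if sample_id is None:
        sample_id = Path(path).stem
    profile = TaxonomicProfile(sample_id=sample_id)
    with open(path, newline="", encoding="utf-8") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError(path, line_no, "expected two columns (genus, abundance)")
            genus = row[0].strip()
            try:
                abundance = int(row[1].strip())
            except ValueError:
                raise ParseError(
                    path, line_no, f"non-integer abundance {row[1]!r}"
                ) from None
            if abundance < 0:
                raise ParseError(path, line_no, f"negative abundance {abundance}")
            taxon_id = index.resolve(genus)
            if taxon_id is None:
                profile.no_hits += abundance
            else:
                profile.counts[taxon_id] = profile.counts.get(taxon_id, 0) + abundance
    return profile


def summarize(profile: TaxonomicProfile, tree: TaxonomyTree) -> dict[int, int]:
    """Subtree totals: each node's own reads plus all reads below it.

    Every ancestor of a counted taxon appears in the result, so the
    root's value equals the profile's assigned total.
    """
    totals: dict[int, int] = {}
    for taxon_id, count in profile.counts.items():
        if taxon_id not in tree:
            raise KeyError(f"profile taxon {taxon_id} absent from tree")
        for ancestor in tree.ancestors(taxon_id):
            totals[ancestor] = totals.get(ancestor, 0) + count
    return totals


@dataclass
class ComparisonTable:
    """Raw and summarized count matrices over a shared taxon row set.

    Rows cover the ancestor-closure of every taxon observed in any
    profile (ordered by depth-first traversal of the tree), so the
    summarized recurrence ``summarized[t] = raw[t] + sum over children``
    holds at every row and the root row carries each column's total.
    """

    taxa: list[int]
    columns: list[str]
    values: np.ndarray  # shape (len(taxa), len(columns)), ints
    summarized: np.ndarray  # same shape

    def to_frame(
        self,
        tree: TaxonomyTree | None = None,
        names: Mapping[int, str] | None = None,
    ) -> pd.DataFrame:
        names = names or {}
        data: dict[str, object] = {
            "taxon_id": self.taxa,
            "taxon_name": [names.get(t, "") for t in self.taxa],
            "rank": [
                tree.rank(t) if tree is not None and t in tree else ""
                for t in self.taxa
            ],
        }
        for j, col in enumerate(self.columns):
            data[f"{col}:raw"] = self.values[:, j]
            data[f"{col}:summarized"] = self.summarized[:, j]
        return pd.DataFrame(data)


def _preorder(tree: TaxonomyTree, keep: set[int]) -> list[int]:
    """Depth-first preorder over the tree restricted to *keep* nodes.

    *keep* must be ancestor-closed (it is, by construction in
    :func:`build_comparison`), so walking only kept children reaches
    every kept node.
    """
    children = tree.children()
    order: list[int] = []
    stack = [tree.root_id] if tree.root_id in keep else []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed([c for c in children[node] if c in keep]))
    return order


def build_comparison(
    profiles: Sequence[TaxonomicProfile], tree: TaxonomyTree
) -> ComparisonTable:
    """Assemble profiles into one table on the union of their taxa.

    The row set is the union of all counted taxa plus their ancestors
    (zero-filled raw counts where a sample lacks a taxon); one raw and
    one summarized column per input profile, in input order.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    keep: set[int] = set()
    for profile in profiles:
        for taxon_id in profile.counts:
            if taxon_id not in tree:
                raise KeyError(f"profile taxon {taxon_id} absent from tree")
            keep.update(tree.ancestors(taxon_id))
    if not keep:
        keep = {tree.root_id}
    taxa = _preorder(tree, keep)
    row_of = {tid: i for i, tid in enumerate(taxa)}
    columns = [p.sample_id for p in profiles]
    values = np.zeros((len(taxa), len(profiles)), dtype=np.int64)
    summarized_m = np.zeros_like(values)
    for j, profile in enumerate(profiles):
        for taxon_id, count in profile.counts.items():
            values[row_of[taxon_id], j] = count
        for taxon_id, total in summarize(profile, tree).items():
            summarized_m[row_of[taxon_id], j] = total
    return ComparisonTable(taxa, columns, values, summarized_m)


def write_comparison(
    table: ComparisonTable,
    path: str | Path,
    tree: TaxonomyTree | None = None,
    names: Mapping[int, str] | None = None,
) -> None:
    """Write the comparison table as TSV."""
    table.to_frame(tree=tree, names=names).to_csv(path, sep="\t", index=False)
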