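"""Shared fixtures: worked-example name index, hand-built trees, bundles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from silvamap import (
    NameClass,
    NameIndex,
    SilvaEntry,
    TaxonRecord,
    TaxonomyTree,
    build_name_index,
)
from silvamap.fixtures import FixtureParams, generate_bundle

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

# Name/ID pairs for the printed worked examples: the full-name match,
# the blocked-name path climb ending at Fusibacter, and the
# environmental-samples skip resolving at Nematoda.
WORKED_EXAMPLE_NAMES = [
    (336503, "Homalopoma granuliferum"),
    (76008, "Fusibacter"),
    (6231, "Nematoda"),
    (2, "Bacteria"),
    (1239, "Firmicutes"),
    (2759, "Eukaryota"),
    (33208, "Metazoa"),
    (69571, "Turbinidae"),
]

WORKED_EXAMPLE_ENTRIES = [
    SilvaEntry(
        "AB365303",
        ("Eukaryota", "Metazoa", "Turbinidae", "Homalopoma"),
        "Homalopoma granuliferum",
    ),
    SilvaEntry(
        "AY548990",
        ("Bacteria", "Firmicutes", "Family XII Incertae Sedis", "Fusibacter"),
        "uncultured bacterium",
    ),
    SilvaEntry(
        "AY763126",
        ("Eukaryota", "Metazoa", "Nematoda", "environmental samples"),
        "uncultured nematode",
    ),
]


@pytest.fixture(scope="session")
def worked_index() -> NameIndex:
    return build_name_index(
        [TaxonRecord(tid, name, NameClass.SCIENTIFIC) for tid, name in WORKED_EXAMPLE_NAMES]
    )


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """Three-level hand tree: root → 2 phyla → genera → species."""
    return TaxonomyTree(
        {
            1: (1, "no rank"),
            2: (1, "superkingdom"),
            3: (2, "phylum"),
            4: (3, "genus"),
            5: (3, "genus"),
            6: (4, "species"),
            7: (4, "species"),
            8: (5, "species"),
            9: (2, "phylum"),
            10: (9, "genus"),
            11: (10, "species"),
        }
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i's parent is uniform among 1..i-1."""
    nodes = {1: (1, "no rank")}
    for tid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, tid))
        nodes[tid] = (parent, "no rank")
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, ids: set[int]) -> int:
    """Oracle: deepest member of the intersection of all root paths."""
    common = set(tree.ancestors(next(iter(ids))))
    for tid in ids:
        common &= set(tree.ancestors(tid))
    return max(common, key=tree.depth)


def iterative_min_support(
    counts: dict[int, int], tree: TaxonomyTree, min_support: int
) -> dict[int, int]:
    """Oracle: repeatedly push the deepest deficient node until stable."""
    counts = dict(counts)
    while True:
        deficient = [
            tid
            for tid, c in counts.items()
            if tid != tree.root_id and 0 < c < min_support
        ]
        if not deficient:
            break
        tid = sorted(deficient, key=lambda t: (-tree.depth(t), t))[0]
        parent = tree.parent(tid)
        counts[parent] = counts.get(parent, 0) + counts.pop(tid)
    return {t: c for t, c in counts.items() if c > 0}


def brute_force_summarize(
    counts: dict[int, int], tree: TaxonomyTree
) -> dict[int, int]:
    """Oracle: per-node exhaustive subtree walk."""
    children = tree.children()
    totals: dict[int, int] = {}

    def subtree_sum(node: int) -> int:
        total = counts.get(node, 0)
        for child in children[node]:
            total += subtree_sum(child)
        return total

    for node in tree:
        total = subtree_sum(node)
        if total:
            totals[node] = total
    return totals


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-mix fixture set (decoys, low-score and unmappable records)."""
    out = tmp_path_factory.mktemp("bundle")
    paths, manifest = generate_bundle(out, FixtureParams(), seed=42)
    return paths, manifest


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free fixture set: every read hits only its true accession."""
    out = tmp_path_factory.mktemp("clean_bundle")
    params = FixtureParams(
        decoy_fraction=0.0,
        low_score_fraction=0.0,
        unmapped_read_fraction=0.0,
        unmappable_fraction=0.0,
    )
    paths, manifest = generate_bundle(out, params, seed=42)
    return paths, manifest
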