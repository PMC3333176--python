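"""LCA binning of BLAST hits into a taxonomic profile.

Reads are aligned (elsewhere) against a 16S reference database with
BLASTN; this module consumes the standard 12-column tabular output and
turns it into per-read NCBI taxon assignments:

* **Min Score** (default 120 bits): hits below are discarded; a read
  whose hits all fail is *unassigned-low-score*.
* **Top Percent** (default 10): among surviving hits only those within
  10% of the best bit score are kept for the LCA.
* The retained hits' accessions are translated to taxon ids through the
  mapping file; the read is assigned to the lowest common ancestor of
  those taxa.  Reads whose retained accessions are all absent from the
  mapping are *unmapped-accession*.
* **Min Support** (default 5): after all reads are binned, any taxon
  attracting fewer reads has them pushed up to its parent, repeatedly,
  so every reported taxon (except the root) meets the threshold.

The default thresholds give a conservative assignment: ambiguous reads
land on higher (less specific) taxa rather than being forced to a
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mapping import MappingFile, read_mapping_file
from .taxonomy import ParseError, TaxonomyTree, parse_names_dump, parse_nodes_dump

log = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "AssignmentParams",
    "ReadAssignment",
    "TaxonomicProfile",
    "STATUS_ASSIGNED",
    "STATUS_NO_HITS",
    "STATUS_LOW_SCORE",
    "STATUS_UNMAPPED",
    "parse_blast_tabular",
    "filter_hits",
    "assign_read",
    "assign_reads",
    "profile_from_assignments",
    "apply_min_support",
    "collapse_at_rank",
    "run_assignment",
    "write_profile",
    "read_profile",
]

STATUS_ASSIGNED = "assigned"
STATUS_NO_HITS = "no-hits"
STATUS_LOW_SCORE = "unassigned-low-score"
STATUS_UNMAPPED = "unmapped-accession"

#: Labels used for the special bins in profile files.
_BIN_LABELS = {
    "no_hits": "No hits",
    "unassigned": "Unassigned (low score)",
    "unmapped": "Unmapped accession",
}


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")


@dataclass(frozen=True)
class AssignmentParams:
    """Binning thresholds; defaults are the conservative standard set."""

    min_score: float = 120.0
    top_percent: float = 10.0
    min_support: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.top_percent <= 100):
            raise ValueError("top_percent must be in (0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str
    taxon_id: int | None = None


@dataclass
class TaxonomicProfile:
    """Per-sample taxon → read-count table plus special bins.

    Invariant: sum of counts + no_hits + unassigned + unmapped equals
    the number of reads processed.
    """

    sample_id: str = "sample"
    counts: dict[int, int] = field(default_factory=dict)
    no_hits: int = 0
    unassigned: int = 0
    unmapped: int = 0

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned_total + self.no_hits + self.unassigned + self.unmapped


def parse_blast_tabular(path: str | Path) -> dict[str, list[BlastHit]]:
    """Parse 12-column BLAST tabular output, grouped by query.

    Columns: query, subject, % identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bit score.  Comment
    lines (``#``) are ignored; any other line with a different column
    count raises :class:`ParseError`.  Hit order within a query is
    preserved.
    """
    hits: dict[str, list[BlastHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(path, line_no, f"expected 12 columns, got {len(fields)}")
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_accession=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
            hits.setdefault(hit.query_id, []).append(hit)
    return hits


def _dedupe_hits(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Collapse multiple HSPs to the same accession, keeping the best score."""
    best: dict[str, BlastHit] = {}
    order: list[str] = []
    for hit in hits:
        acc = hit.subject_accession
        if acc not in best:
            best[acc] = hit
            order.append(acc)
        elif hit.bit_score > best[acc].bit_score:
            best[acc] = hit
    return [best[acc] for acc in order]


def filter_hits(hits: Sequence[BlastHit], params: AssignmentParams) -> list[BlastHit]:
    """Apply the Min Score and Top Percent filters.

    Hits with ``bit_score < min_score`` are dropped; among the
    survivors only those within ``top_percent`` percent of the best
    surviving bit score are retained (band
    ``[best * (1 - top_percent/100), best]``).  Input order preserved.
    """
    survivors = [h for h in hits if h.bit_score >= params.min_score]
    if not survivors:
        return []
    best = max(h.bit_score for h in survivors)
    threshold = best * (1.0 - params.top_percent / 100.0)
    return [h for h in survivors if h.bit_score >= threshold]


def assign_read(
    read_id: str,
    hits: Sequence[BlastHit],
    mapping: MappingFile,
    tree: TaxonomyTree,
    params: AssignmentParams = AssignmentParams(),
) -> ReadAssignment:
    """Assign one read: filter its hits, translate accessions, take the LCA."""
    if not hits:
        return ReadAssignment(read_id, STATUS_NO_HITS)
    deduped = _dedupe_hits(hits)
    scored = [h for h in deduped if h.bit_score >= params.min_score]
    if not scored:
        return ReadAssignment(read_id, STATUS_LOW_SCORE)
    retained = filter_hits(scored, params)
    taxa: set[int] = set()
    for hit in retained:
        taxon_id = mapping.get(hit.subject_accession)
        if taxon_id is None:
            continue
        if taxon_id not in tree:
            raise KeyError(
                f"accession {hit.subject_accession} maps to taxon {taxon_id}, "
                "which is absent from the taxonomy tree"
            )
        taxa.add(taxon_id)
    if not taxa:
        return ReadAssignment(read_id, STATUS_UNMAPPED)
    return ReadAssignment(read_id, STATUS_ASSIGNED, tree.lca(taxa))


def assign_reads(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    mapping: MappingFile,
    tree: TaxonomyTree,
    params: AssignmentParams = AssignmentParams(),
) -> list[ReadAssignment]:
    """Assign every read, in sorted read-id order for determinism."""
    return [
        assign_read(read_id, hits_by_query[read_id], mapping, tree, params)
        for read_id in sorted(hits_by_query)
    ]


def profile_from_assignments(
    assignments: Iterable[ReadAssignment], sample_id: str = "sample"
) -> TaxonomicProfile:
    profile = TaxonomicProfile(sample_id=sample_id)
    for a in assignments:
        if a.status == STATUS_ASSIGNED:
            assert a.taxon_id is not None
            profile.counts[a.taxon_id] = profile.counts.get(a.taxon_id, 0) + 1
        elif a.status == STATUS_NO_HITS:
            profile.no_hits += 1
        elif a.status == STATUS_LOW_SCORE:
            profile.unassigned += 1
        elif a.status == STATUS_UNMAPPED:
            profile.unmapped += 1
        else:  # pragma: no cover - guarded by ReadAssignment construction
            raise ValueError(f"unknown status {a.status!r}")
    return profile


def apply_min_support(
    profile: TaxonomicProfile,
    tree: TaxonomyTree,
    params: AssignmentParams = AssignmentParams(),
) -> TaxonomicProfile:
    """Push reads on under-supported taxa up to their parents.

    Nodes are processed deepest-first in a single sweep; counts are
    re-examined as pushed-up reads arrive, so a parent that becomes
    under-supported after absorbing its children is itself pushed up
    when its turn comes.  The root retains whatever reaches it.  Total
    read count is conserved.
    """
    counts = dict(profile.counts)
    unknown = [tid for tid in counts if tid not in tree]
    if unknown:
        raise KeyError(f"profile taxa absent from tree: {sorted(unknown)}")
    order = sorted(tree, key=lambda tid: (-tree.depth(tid), tid))
    for tid in order:
        if tid == tree.root_id:
            continue
        count = counts.get(tid, 0)
        if 0 < count < params.min_support:
            parent = tree.parent(tid)
            counts[parent] = counts.get(parent, 0) + count
            del counts[tid]
    counts = {tid: c for tid, c in counts.items() if c > 0}
    return replace(profile, counts=counts)


def collapse_at_rank(
    profile: TaxonomicProfile, tree: TaxonomyTree, rank: str
) -> TaxonomicProfile:
    """Accumulate each taxon's count onto its nearest ancestor of *rank*.

    Ancestor-or-self: a count already sitting at the rank stays put.
    Taxa with no ancestor of the rank keep their own bin.  Totals are
    conserved.
    """
    if rank not in tree.ranks:
        raise ValueError(f"rank {rank!r} does not occur in the taxonomy")
    collapsed: dict[int, int] = {}
    for taxon_id, count in profile.counts.items():
        target = taxon_id
        for ancestor in tree.ancestors(taxon_id):
            if tree.rank(ancestor) == rank:
                target = ancestor
                break
        collapsed[target] = collapsed.get(target, 0) + count
    return replace(profile, counts=collapsed)


def run_assignment(
    blast_path: str | Path,
    mapping_path: str | Path,
    names_path: str | Path,
    nodes_path: str | Path,
    params: AssignmentParams = AssignmentParams(),
    sample_id: str | None = None,
    rank: str | None = None,
) -> TaxonomicProfile:
    """Full pipeline: parse inputs, assign reads, min-support, collapse.

    ``names_path`` is parsed for validation and logging (taxon names in
    the summary); the assignment itself needs only the mapping and the
    node tree.  If *rank* is given the profile is collapsed at it after
    the min-support push-up.
    """
    hits_by_query = parse_blast_tabular(blast_path)
    mapping = read_mapping_file(mapping_path)
    parse_names_dump(names_path)  # validated; names are presentation-only
    tree = parse_nodes_dump(nodes_path)
    if sample_id is None:
        sample_id = Path(blast_path).stem
    assignments = assign_reads(hits_by_query, mapping, tree, params)
    profile = profile_from_assignments(assignments, sample_id=sample_id)
    log.info(
        "sample %s: %d reads — assigned=%d, no-hits=%d, low-score=%d, unmapped=%d",
        sample_id,
        profile.total,
        profile.assigned_total,
        profile.no_hits,
        profile.unassigned,
        profile.unmapped,
    )
    profile = apply_min_support(profile, tree, params)
    if rank is not None:
        profile = collapse_at_rank(profile, tree, rank)
    return profile


def write_profile(
    profile: TaxonomicProfile,
    path: str | Path,
    tree: TaxonomyTree | None = None,
    names: Mapping[int, str] | None = None,
) -> None:
    """Write a profile as TSV: taxon_id, taxon_name, rank, count.

    Taxa are sorted by count descending then taxon id; the special bins
    follow as pseudo-rows with ``-`` in the taxon_id column.
    """
    names = names or {}
    rows = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample\t{profile.sample_id}\n")
        fh.write("taxon_id\ttaxon_name\trank\tcount\n")
        for taxon_id, count in rows:
            name = names.get(taxon_id, "")
            rank = tree.rank(taxon_id) if tree is not None and taxon_id in tree else ""
            fh.write(f"{taxon_id}\t{name}\t{rank}\t{count}\n")
        for attr, label in _BIN_LABELS.items():
            fh.write(f"-\t{label}\t\t{getattr(profile, attr)}\n")


def read_profile(path: str | Path) -> TaxonomicProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    label_to_attr = {label: attr for attr, label in _BIN_LABELS.items()}
    profile = TaxonomicProfile(sample_id=Path(path).stem)
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("# sample\t"):
                profile.sample_id = line.split("\t", 1)[1]
                continue
            if line.startswith("#") or line.startswith("taxon_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, got {len(fields)}")
            try:
                count = int(fields[3])
            except ValueError:
                raise ParseError(path, line_no, f"non-integer count {fields[3]!r}") from None
            if fields[0] == "-":
                attr = label_to_attr.get(fields[1])
                if attr is None:
                    raise ParseError(path, line_no, f"unknown special bin {fields[1]!r}")
                setattr(profile, attr, count)
            else:
                try:
                    taxon_id = int(fields[0])
                except ValueError:
                    raise ParseError(path, line_no, f"non-integer taxon id {fields[0]!r}") from None
                profile.counts[taxon_id] = profile.counts.get(taxon_id, 0) + count
    return profile
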