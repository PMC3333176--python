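"""The accession-to-taxid mapping ("synonym file") algorithm.

A SILVA export record carries a full organism name and a taxonomic
path, but no NCBI taxon id.  The mapping algorithm resolves each record
against the NCBI name index:

1. If the full name is usable (it does not contain one of the blocked
   keywords ``uncultured`` / ``unidentified`` / ``metagenome``) and the
   name index knows it, the record maps to that taxon — a *full-name
   match*.
2. If the full name is blocked, the taxonomic path is climbed from its
   lowest (most specific) element upwards until an element resolves;
   path elements containing ``environmental samples`` are skipped.
   That is a *path match*.
3. A usable full name that simply is not in the index is retried with
   changed capitalization (all-lower, sentence case, title case); a
   variant hit is a *capitalization retry* match.  If the variants also
   miss, the path climb of step 2 is used as fallback.
4. Records that survive none of the above stay *unmapped*; they are
   counted but never written to the mapping file.

Keyword matching is case-insensitive substring containment throughout.
The output is a two-column tab-separated file (accession, taxon id)
suitable for accession-lookup import into downstream binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from .silva_export import SilvaEntry
from .taxonomy import NameIndex, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "BlockedKeywords",
    "DEFAULT_KEYWORDS",
    "MappingFile",
    "PROV_FULL_NAME",
    "PROV_CAPITALIZATION",
    "PROV_UNMAPPED",
    "is_blocked_name",
    "capitalization_variants",
    "search_full_taxa",
    "map_entry",
    "build_mapping",
    "write_mapping_file",
    "read_mapping_file",
]

PROV_FULL_NAME = "full-name match"
PROV_CAPITALIZATION = "capitalization retry"
PROV_UNMAPPED = "unmapped"


def _prov_path(depth: int) -> str:
    return f"path match at depth {depth}"


@dataclass(frozen=True)
class BlockedKeywords:
    """Keywords that disqualify a name (or a path element) from matching.

    ``name_keywords`` divert a record from full-name matching to the
    path climb; ``path_keywords`` make the climb skip an element.
    Matching is case-insensitive substring containment.
    """

    name_keywords: frozenset[str] = frozenset({"uncultured", "unidentified", "metagenome"})
    path_keywords: frozenset[str] = frozenset({"environmental samples"})


DEFAULT_KEYWORDS = BlockedKeywords()


def is_blocked_name(name: str, keywords: BlockedKeywords = DEFAULT_KEYWORDS) -> bool:
    """True iff any name keyword occurs (case-insensitively) in *name*."""
    lowered = name.lower()
    return any(kw.lower() in lowered for kw in keywords.name_keywords)


def _is_blocked_path_element(element: str, keywords: BlockedKeywords) -> bool:
    lowered = element.lower()
    return any(kw.lower() in lowered for kw in keywords.path_keywords)


def capitalization_variants(name: str) -> list[str]:
    """Deterministic case variants to retry when an exact lookup misses.

    In order: all-lowercase, first-letter-uppercased-rest-lower
    (sentence case), each-word-capitalized (title case).  The original
    form is excluded and duplicates removed, preserving order.
    """
    lowered = name.lower()
    sentence = lowered[:1].upper() + lowered[1:]
    title = " ".join(w[:1].upper() + w[1:] for w in lowered.split(" "))
    variants: list[str] = []
    for candidate in (lowered, sentence, title):
        if candidate != name and candidate not in variants:
            variants.append(candidate)
    return variants


def _resolve_with_variants(
    name: str, index: NameIndex, retry_capitalization: bool
) -> tuple[int | None, bool]:
    """Resolve a name, optionally retrying case variants.

    Returns (taxon_id or None, used_variant flag).
    """
    taxon_id = index.resolve(name)
    if taxon_id is not None:
        return taxon_id, False
    if retry_capitalization:
        for variant in capitalization_variants(name):
            taxon_id = index.resolve(variant)
            if taxon_id is not None:
                return taxon_id, True
    return None, False


def _climb_path(
    path: Sequence[str],
    index: NameIndex,
    keywords: BlockedKeywords,
    retry_capitalization: bool,
) -> tuple[int, int] | None:
    """Climb the path lowest-first; return (taxon_id, depth) or None.

    Depth is the element's index in the path (0 = highest rank), so a
    deeper (more specific) hit has a larger depth.
    """
    for depth in range(len(path) - 1, -1, -1):
        element = path[depth]
        if _is_blocked_path_element(element, keywords):
            continue
        taxon_id, _ = _resolve_with_variants(element, index, retry_capitalization)
        if taxon_id is not None:
            return taxon_id, depth
    return None


def search_full_taxa(
    path: Sequence[str],
    index: NameIndex,
    keywords: BlockedKeywords = DEFAULT_KEYWORDS,
    retry_capitalization: bool = True,
) -> int | None:
    """Resolve a taxonomic path to the deepest matchable element's taxon.

    Iterates from the lowest (last) element to the highest, skipping
    elements that contain a path keyword such as ``environmental
    samples``; returns the first element that resolves, or ``None`` if
    the climb exhausts the path.
    """
    hit = _climb_path(path, index, keywords, retry_capitalization)
    return None if hit is None else hit[0]


def map_entry(
    entry: SilvaEntry,
    index: NameIndex,
    keywords: BlockedKeywords = DEFAULT_KEYWORDS,
) -> tuple[int | None, str]:
    """Map one SILVA record to a taxon id, returning (id, provenance).

    Provenance is one of ``full-name match``, ``path match at depth d``,
    ``capitalization retry`` or ``unmapped`` (in which case the id is
    ``None``).
    """
    name = entry.full_name
    if name and not is_blocked_name(name, keywords):
        taxon_id = index.resolve(name)
        if taxon_id is not None:
            return taxon_id, PROV_FULL_NAME
        for variant in capitalization_variants(name):
            taxon_id = index.resolve(variant)
            if taxon_id is not None:
                return taxon_id, PROV_CAPITALIZATION
    hit = _climb_path(entry.taxonomic_path, index, keywords, retry_capitalization=True)
    if hit is not None:
        return hit[0], _prov_path(hit[1])
    return None, PROV_UNMAPPED


@dataclass
class MappingFile:
    """Accession → taxon id table plus per-accession provenance.

    ``provenance`` also records accessions that ended up unmapped (they
    are absent from ``rows``), so mapping-rate summaries are complete.
    """

    rows: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, accession: str) -> int | None:
        return self.rows.get(accession)

    def summary(self) -> Counter[str]:
        """Counts per provenance category (path matches pooled)."""
        counts: Counter[str] = Counter()
        for prov in self.provenance.values():
            key = "path match" if prov.startswith("path match") else prov
            counts[key] += 1
        return counts


def build_mapping(
    entries: Iterable[SilvaEntry],
    index: NameIndex,
    keywords: BlockedKeywords = DEFAULT_KEYWORDS,
) -> MappingFile:
    """Run the mapping algorithm over all entries.

    Duplicate accessions are tolerated with a warning; the last
    occurrence wins.  Unmapped records are excluded from ``rows`` but
    reflected in :meth:`MappingFile.summary`.
    """
    mapping = MappingFile()
    for entry in entries:
        if entry.accession in mapping.provenance:
            log.warning("duplicate accession %s: last occurrence wins", entry.accession)
            mapping.rows.pop(entry.accession, None)
        taxon_id, provenance = map_entry(entry, index, keywords)
        mapping.provenance[entry.accession] = provenance
        if taxon_id is not None:
            mapping.rows[entry.accession] = taxon_id
    counts = mapping.summary()
    log.info(
        "mapping built: %d/%d accessions mapped (%s)",
        len(mapping.rows),
        len(mapping.provenance),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return mapping


def write_mapping_file(mapping: MappingFile, path: str | Path) -> None:
    """Write the two-column (accession TAB taxon id) mapping file.

    Rows are sorted by accession so identical inputs give byte-identical
    files.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for accession in sorted(mapping.rows):
            fh.write(f"{accession}\t{mapping.rows[accession]}\n")


def read_mapping_file(path: str | Path) -> MappingFile:
    """Read a mapping file back; inverse of :func:`write_mapping_file` on rows."""
    mapping = MappingFile()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, line_no, f"expected 2 columns, got {len(fields)}")
            accession = fields[0].strip()
            try:
                taxon_id = int(fields[1].strip())
            except ValueError:
                raise ParseError(path, line_no, f"non-integer taxon id {fields[1]!r}") from None
            if not accession:
                raise ParseError(path, line_no, "empty accession")
            mapping.rows[accession] = taxon_id
    return mapping
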