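"""Parsing the SILVA ARB "NDS field export" flat file.

The export is one record per line with (at least) three columns:
accession, semicolon-separated taxonomic path (highest rank first), and
the organism's full name (which may be empty, e.g. for environmental
clones).  The column delimiter defaults to tab — ARB's NDS export
default — but is configurable for exports produced with other settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .taxonomy import ParseError

__all__ = ["SilvaEntry", "parse_silva_export", "write_silva_export"]


@dataclass(frozen=True)
class SilvaEntry:
    """One exported SILVA record.

    ``taxonomic_path`` is ordered highest rank first (e.g. Bacteria at
    index 0) and never contains empty elements.
    """

    accession: str
    taxonomic_path: tuple[str, ...]
    full_name: str = ""

    def __post_init__(self) -> None:
        if not self.accession.strip():
            raise ValueError("accession must be non-empty")
        object.__setattr__(self, "accession", self.accession.strip())
        path = tuple(p.strip() for p in self.taxonomic_path if p.strip())
        if not path:
            raise ValueError("taxonomic path must be non-empty")
        object.__setattr__(self, "taxonomic_path", path)
        object.__setattr__(self, "full_name", self.full_name.strip())


def parse_silva_export(path: str | Path, delimiter: str = "\t") -> list[SilvaEntry]:
    """Parse an NDS-export file into :class:`SilvaEntry` records.

    Path elements are split on ``;`` and trimmed; empty elements (such
    as the one produced by a trailing semicolon) are dropped.  A line
    with a missing accession or an empty path raises :class:`ParseError`
    carrying the line number.
    """
    entries: list[SilvaEntry] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    path, line_no, f"expected >=2 delimited columns, got {len(fields)}"
                )
            accession = fields[0].strip()
            path_elements = tuple(
                el.strip() for el in fields[1].split(";") if el.strip()
            )
            full_name = fields[2].strip() if len(fields) > 2 else ""
            if not accession:
                raise ParseError(path, line_no, "missing accession")
            if not path_elements:
                raise ParseError(path, line_no, "empty taxonomic path")
            entries.append(SilvaEntry(accession, path_elements, full_name))
    return entries


def write_silva_export(
    entries: Iterable[SilvaEntry], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write entries in the same dialect :func:`parse_silva_export` reads.

    Round-trip safe: ``parse(write(entries)) == entries``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for entry in entries:
            fh.write(
                delimiter.join(
                    (entry.accession, "; ".join(entry.taxonomic_path) + ";", entry.full_name)
                )
                + "\n"
            )
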