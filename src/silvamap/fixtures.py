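"""Synthetic taxonomies, SILVA exports and BLAST tables with ground truth.

Every stage of the pipeline is testable without downloading the real
NCBI taxdump or SILVA database: this module fabricates

* a names.dmp / nodes.dmp pair over a randomly branched tree that
  follows the canonical rank ladder (superkingdom … genus, species),
  with a configurable share of synonym records, deliberate homonyms,
  and one ``environmental samples`` pseudo-genus to exercise the
  path-keyword skip;
* a SILVA NDS-style export whose records' paths are the true lineages,
  with configurable fractions of blocked full names (``uncultured …``),
  case-mangled names (capitalization-retry exercise) and unmappable
  records;
* a BLAST 12-column tabular file in which every simulated read hits its
  true source accession with the top bit score, plus optional decoy
  hits to other accessions and a fraction of reads whose hits all fall
  below the default Min Score.

A :class:`FixtureManifest` records the generating truth (topology,
names, the taxon every accession should map to, every read's source
accession and intended assignment status), so tests compare pipeline
output against the manifest rather than against re-derived values.

Determinism: each generator draws from its own stream seeded by
``(seed, generator-name)``, so outputs are byte-identical across runs
and adding one generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assignment import STATUS_ASSIGNED, STATUS_LOW_SCORE, STATUS_UNMAPPED
from .silva_export import SilvaEntry, write_silva_export
from .taxonomy import NameClass, TaxonRecord

__all__ = [
    "RANK_LADDER",
    "FixtureParams",
    "FixtureManifest",
    "generate_taxonomy",
    "generate_silva_export",
    "generate_blast_tabular",
    "generate_bundle",
    "write_manifest",
]

RANK_LADDER = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_SYLLABLES = (
    "ba", "cro", "di", "fex", "ga", "hu", "lo", "mi", "nor", "pra",
    "qui", "ro", "sta", "tu", "vel", "xan", "ze", "phi", "cus", "ter",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent stream per generator: seeded by (seed, crc32(stream))."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode()) & 0x7FFFFFFF])


def _pseudo_word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        _SYLLABLES[int(rng.integers(len(_SYLLABLES)))] for _ in range(n_syllables)
    )


def _fresh_name(rng: np.random.Generator, used: set[str], capitalize: bool = True) -> str:
    while True:
        word = _pseudo_word(rng)
        name = word.capitalize() if capitalize else word
        if name not in used:
            used.add(name)
            return name


@dataclass(frozen=True)
class FixtureParams:
    """Knobs for the synthetic study conditions.

    Fractions are in [0, 1]; score bounds are (low, high) bit scores.
    The defaults give a medium-sized community with a realistic mix of
    well-named, environmental-clone and undatabased records.
    """

    n_taxa: int = 200
    n_accessions: int = 500
    n_reads: int = 2000
    synonym_fraction: float = 0.3
    homonym_fraction: float = 0.05
    blocked_fraction: float = 0.2
    case_mangled_fraction: float = 0.1
    unmappable_fraction: float = 0.05
    decoy_fraction: float = 0.3
    low_score_fraction: float = 0.05
    unmapped_read_fraction: float = 0.05
    max_decoys: int = 3
    score_bounds: tuple[float, float] = (150.0, 400.0)
    low_score_bounds: tuple[float, float] = (40.0, 115.0)

    def __post_init__(self) -> None:
        for name in (
            "synonym_fraction",
            "homonym_fraction",
            "blocked_fraction",
            "case_mangled_fraction",
            "unmappable_fraction",
            "decoy_fraction",
            "low_score_fraction",
            "unmapped_read_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.score_bounds[0] > self.score_bounds[1]:
            raise ValueError("score_bounds must be ordered")
        if self.low_score_bounds[0] > self.low_score_bounds[1]:
            raise ValueError("low_score_bounds must be ordered")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")


@dataclass
class FixtureManifest:
    """Ground truth behind a generated fixture set."""

    seed: int
    params: FixtureParams
    nodes: dict[int, tuple[int, str]] = field(default_factory=dict)
    scientific_name: dict[int, str] = field(default_factory=dict)
    records: list[TaxonRecord] = field(default_factory=list)
    env_samples_id: int | None = None
    entries: list[SilvaEntry] = field(default_factory=list)
    #: accession -> taxon the mapping algorithm should emit (None = unmappable)
    accession_expected: dict[str, int | None] = field(default_factory=dict)
    #: accession -> species the sequence was "drawn" from
    accession_source: dict[str, int] = field(default_factory=dict)
    #: (read_id, source accession, intended assignment status)
    reads: list[tuple[str, str, str]] = field(default_factory=list)

    def lineage_names(self, taxon_id: int) -> list[str]:
        """Names from just below the root down to the taxon itself."""
        path: list[int] = []
        tid = taxon_id
        while self.nodes[tid][0] != tid:
            path.append(tid)
            tid = self.nodes[tid][0]
        return [self.scientific_name[t] for t in reversed(path)]

    def intended_status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, status in self.reads:
            counts[status] = counts.get(status, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# taxonomy generator


def _level_sizes(n_internal: int, n_levels: int, growth: float = 1.6) -> list[int]:
    """Split n_internal nodes over n_levels, sizes growing geometrically.

    Requires ``n_internal >= n_levels`` (each level gets at least one
    node); callers truncate the rank ladder for smaller trees.
    """
    if n_internal < n_levels:
        raise ValueError("need at least one node per level")
    weights = np.array([growth**i for i in range(n_levels)])
    raw = weights / weights.sum() * n_internal
    sizes = np.maximum(1, np.floor(raw).astype(int))
    while sizes.sum() < n_internal:
        sizes[-1] += 1
    while sizes.sum() > n_internal:
        for i in range(n_levels - 1, -1, -1):
            if sizes.sum() <= n_internal:
                break
            if sizes[i] > 1:
                sizes[i] -= 1
    return sizes.tolist()


def generate_taxonomy(
    out_dir: str | Path,
    params: FixtureParams = FixtureParams(),
    seed: int = 0,
) -> tuple[Path, Path, FixtureManifest]:
    """Write synthetic names.dmp / nodes.dmp and return them with the truth.

    The tree has the full rank ladder; every level-``i`` node gets a
    random parent from level ``i-1``.  A share of taxa receive synonym
    or equivalent-name records; a share of those synonyms duplicate
    another taxon's scientific name (deliberate homonyms).  One extra
    node named ``environmental samples`` is inserted at genus level
    with a few species beneath it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, "taxonomy")
    manifest = FixtureManifest(seed=seed, params=params)

    root_id = 1
    manifest.nodes[root_id] = (root_id, "no rank")
    manifest.scientific_name[root_id] = "root"

    n_internal = params.n_taxa - 1
    ladder = RANK_LADDER[: min(len(RANK_LADDER), n_internal)]
    sizes = _level_sizes(n_internal, len(ladder))
    used_names: set[str] = {"root"}
    next_id = 2
    levels: list[list[int]] = [[root_id]]
    for level_index, (rank, size) in enumerate(zip(ladder, sizes), start=1):
        level: list[int] = []
        parents = levels[level_index - 1]
        for _ in range(size):
            parent = parents[int(rng.integers(len(parents)))]
            tid = next_id
            next_id += 1
            manifest.nodes[tid] = (parent, rank)
            if rank == "species":
                genus_name = manifest.scientific_name[parent]
                epithet = _pseudo_word(rng, 2)
                name = f"{genus_name} {epithet}"
                while name in used_names:
                    name = f"{genus_name} {_pseudo_word(rng, 2)}"
                used_names.add(name)
            else:
                name = _fresh_name(rng, used_names)
            manifest.scientific_name[tid] = name
            level.append(tid)
        levels.append(level)

    # environmental-samples pseudo-genus under a random family, with species
    families = [t for t, (_, r) in manifest.nodes.items() if r == "family"]
    if families:
        env_parent = families[int(rng.integers(len(families)))]
        env_id = next_id
        next_id += 1
        manifest.nodes[env_id] = (env_parent, "genus")
        manifest.scientific_name[env_id] = "environmental samples"
        manifest.env_samples_id = env_id
        for _ in range(3):
            tid = next_id
            next_id += 1
            manifest.nodes[tid] = (env_id, "species")
            manifest.scientific_name[tid] = f"{_fresh_name(rng, used_names)} clone"

    # name records: every scientific name, plus synonyms/equivalents/homonyms
    for tid in sorted(manifest.nodes):
        manifest.records.append(
            TaxonRecord(tid, manifest.scientific_name[tid], NameClass.SCIENTIFIC)
        )
    all_ids = sorted(manifest.nodes)
    extra_classes = (NameClass.SYNONYM, NameClass.EQUIVALENT, NameClass.MISSPELLING)
    for tid in all_ids:
        if tid == root_id:
            continue
        if rng.random() < params.synonym_fraction:
            cls = extra_classes[int(rng.integers(len(extra_classes)))]
            if rng.random() < params.homonym_fraction:
                # homonym: reuse another taxon's scientific name as a synonym
                other = all_ids[int(rng.integers(len(all_ids)))]
                name = manifest.scientific_name[other]
            else:
                name = _fresh_name(rng, used_names)
            manifest.records.append(TaxonRecord(tid, name, cls))

    names_path = out_dir / "names.dmp"
    nodes_path = out_dir / "nodes.dmp"
    with open(names_path, "w", encoding="utf-8") as fh:
        for record in manifest.records:
            fh.write(
                f"{record.taxon_id}\t|\t{record.name}\t|\t\t|\t{record.name_class.value}\t|\n"
            )
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tid in sorted(manifest.nodes):
            parent, rank = manifest.nodes[tid]
            fh.write(f"{tid}\t|\t{parent}\t|\t{rank}\t|\n")
    return names_path, nodes_path, manifest


# ---------------------------------------------------------------------------
# SILVA export generator


def generate_silva_export(
    manifest: FixtureManifest,
    out_path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write a synthetic NDS export; records the per-accession truth.

    Each accession is attached to a random species.  Depending on the
    configured fractions a record's full name is the species name
    (full-name match), a case-mangled copy (capitalization retry), an
    ``uncultured``-style blocked name (path climb), or — for unmappable
    records — a name and path entirely outside the taxonomy.
    """
    params = manifest.params
    seed = manifest.seed if seed is None else seed
    rng = _rng(seed, "silva")
    species = sorted(
        t for t, (_, rank) in manifest.nodes.items() if rank == "species"
    )
    if not species:
        raise ValueError("taxonomy too small: no species-rank taxa to draw from")
    env_id = manifest.env_samples_id
    manifest.entries.clear()
    manifest.accession_expected.clear()
    manifest.accession_source.clear()
    for i in range(params.n_accessions):
        accession = f"FX{i:06d}"
        draw = rng.random()
        if draw < params.unmappable_fraction:
            # a record whose name and path exist nowhere in the taxonomy
            fake = _pseudo_word(rng, 4).capitalize()
            entry = SilvaEntry(
                accession,
                (f"{fake}ia", f"{fake}ales", f"{fake}aceae"),
                f"{fake} incognita",
            )
            manifest.accession_expected[accession] = None
        else:
            sp = species[int(rng.integers(len(species)))]
            lineage = manifest.lineage_names(sp)  # superkingdom .. species
            path = tuple(lineage[:-1])  # path stops at genus level
            parent = manifest.nodes[sp][0]
            is_env = parent == env_id
            blocked = is_env or draw < params.unmappable_fraction + params.blocked_fraction
            if blocked:
                kind = int(rng.integers(3))
                if kind == 0:
                    full = f"uncultured {manifest.scientific_name[parent].lower()}"
                elif kind == 1:
                    full = "unidentified organism"
                else:
                    full = f"{manifest.scientific_name[parent].lower()} metagenome"
                # expected: deepest path element that is not path-blocked
                expected = manifest.nodes[parent][0] if is_env else parent
            else:
                full = manifest.scientific_name[sp]
                if (
                    rng.random() < params.case_mangled_fraction
                    and full != full.lower()
                ):
                    full = full.lower()  # recovered by capitalization retry
                expected = sp
            entry = SilvaEntry(accession, path, full)
            manifest.accession_expected[accession] = expected
            manifest.accession_source[accession] = sp
        manifest.entries.append(entry)
    out_path = Path(out_path)
    write_silva_export(manifest.entries, out_path)
    return out_path


# ---------------------------------------------------------------------------
# BLAST tabular generator


def _format_hit(
    read_id: str, accession: str, rng: np.random.Generator, bit_score: float
) -> str:
    identity = float(rng.uniform(90.0, 100.0))
    length = int(rng.integers(200, 500))
    mismatches = int(round(length * (100.0 - identity) / 100.0))
    return (
        f"{read_id}\t{accession}\t{identity:.1f}\t{length}\t{mismatches}\t0"
        f"\t1\t{length}\t1\t{length}\t1e-50\t{bit_score:.1f}\n"
    )


def generate_blast_tabular(
    manifest: FixtureManifest,
    out_path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write a synthetic 12-column BLAST table; records per-read truth.

    Every read's top-scoring hit is its true source accession.  Decoy
    hits (to other accessions, at 60–98% of the top score) are added
    for a fraction of reads; a fraction of reads score entirely below
    the default Min Score of 120 (intended status unassigned-low-score)
    and a fraction hit only undatabased accessions (intended status
    unmapped-accession).
    """
    params = manifest.params
    seed = manifest.seed if seed is None else seed
    rng = _rng(seed, "blast")
    mappable = sorted(
        acc for acc, exp in manifest.accession_expected.items() if exp is not None
    )
    unmappable = sorted(
        acc for acc, exp in manifest.accession_expected.items() if exp is None
    )
    if not mappable:
        raise ValueError("fixture has no mappable accessions")
    all_accessions = sorted(manifest.accession_expected)
    manifest.reads.clear()
    out_path = Path(out_path)
    with open(out_path, "w", encoding="utf-8") as fh:
        for i in range(params.n_reads):
            read_id = f"read{i:06d}"
            draw = rng.random()
            if draw < params.low_score_fraction:
                accession = mappable[int(rng.integers(len(mappable)))]
                score = float(rng.uniform(*params.low_score_bounds))
                fh.write(_format_hit(read_id, accession, rng, score))
                manifest.reads.append((read_id, accession, STATUS_LOW_SCORE))
                continue
            if (
                unmappable
                and draw < params.low_score_fraction + params.unmapped_read_fraction
            ):
                accession = unmappable[int(rng.integers(len(unmappable)))]
                score = float(rng.uniform(*params.score_bounds))
                fh.write(_format_hit(read_id, accession, rng, score))
                manifest.reads.append((read_id, accession, STATUS_UNMAPPED))
                continue
            accession = mappable[int(rng.integers(len(mappable)))]
            top = float(rng.uniform(*params.score_bounds))
            fh.write(_format_hit(read_id, accession, rng, top))
            if rng.random() < params.decoy_fraction:
                for _ in range(1 + int(rng.integers(params.max_decoys))):
                    decoy = all_accessions[int(rng.integers(len(all_accessions)))]
                    if decoy == accession:
                        continue
                    decoy_score = top * float(rng.uniform(0.60, 0.98))
                    fh.write(_format_hit(read_id, decoy, rng, decoy_score))
            manifest.reads.append((read_id, accession, STATUS_ASSIGNED))
    return out_path


# ---------------------------------------------------------------------------
# convenience


def generate_bundle(
    out_dir: str | Path,
    params: FixtureParams = FixtureParams(),
    seed: int = 0,
) -> tuple[dict[str, Path], FixtureManifest]:
    """Generate the full fixture set into one directory.

    Returns a name → path map for names.dmp, nodes.dmp, silva_export.tsv
    and blast_hits.tsv, plus the manifest.
    """
    out_dir = Path(out_dir)
    names_path, nodes_path, manifest = generate_taxonomy(out_dir, params, seed)
    silva_path = generate_silva_export(manifest, out_dir / "silva_export.tsv")
    blast_path = generate_blast_tabular(manifest, out_dir / "blast_hits.tsv")
    return (
        {
            "names": names_path,
            "nodes": nodes_path,
            "silva": silva_path,
            "blast": blast_path,
        },
        manifest,
    )


def write_manifest(manifest: FixtureManifest, out_dir: str | Path) -> list[Path]:
    """Dump the ground truth as TSV files next to the fixture data."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acc_path = out_dir / "manifest_accessions.tsv"
    with open(acc_path, "w", encoding="utf-8") as fh:
        fh.write("accession\tsource_taxon\texpected_taxon\n")
        for acc in sorted(manifest.accession_expected):
            expected = manifest.accession_expected[acc]
            source = manifest.accession_source.get(acc, "")
            fh.write(f"{acc}\t{source}\t{'' if expected is None else expected}\n")
    reads_path = out_dir / "manifest_reads.tsv"
    with open(reads_path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tsource_accession\tintended_status\n")
        for read_id, accession, status in manifest.reads:
            fh.write(f"{read_id}\t{accession}\t{status}\n")
    return [acc_path, reads_path]
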