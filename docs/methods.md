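# Methods

## The problem

16S rRNA amplicon reads are commonly identified by BLASTN against the
SILVA rRNA database, but SILVA hits carry accessions and taxonomic
paths rather than NCBI taxon IDs. Downstream tools that organize
results on the NCBI taxonomy (and that must compare amplicon profiles
with shotgun profiles on the same tree) need a translation layer.
`silvamap` provides that layer as a standalone, testable pipeline:
an accession → taxid mapping-file builder, an LCA read binner with
conservative thresholds, and a profile comparison step.

## Name-matching (mapping) algorithm

A hash map is built over **every** name in `names.dmp`, all classes
included — scientific names, synonyms, equivalent names, misspellings —
because environmental-survey records frequently carry non-canonical
spellings. Keys are normalized only by trimming and collapsing internal
whitespace; matching is case-sensitive on the first attempt so that the
plain hash-map semantics stay observable.

Each SILVA record is then resolved in this order:

1. **Full-name match.** If the full organism name does not contain a
   blocking keyword (`uncultured`, `unidentified`, `metagenome`;
   case-insensitive substring test) and the index knows it, the record
   maps there.
2. **Capitalization retry.** A usable name that misses is retried as
   all-lowercase, sentence case, then title case (original form
   excluded, duplicates dropped). The fixed order makes the retry
   deterministic and testable; the first resolving variant wins.
3. **Path climb** (`search_full_taxa`). Blocked names — and names whose
   retries all miss — fall back to the taxonomic path, scanned from the
   lowest (most specific) element upward. Elements containing
   `environmental samples` are skipped; each element gets the same
   exact-then-case-variant lookup. The first resolving element's taxon
   is taken. Applying the capitalization retry to path elements as well
   as full names is a deliberate symmetry choice; it can only recover
   additional records, never change a first-attempt hit.
4. **Unmapped.** If the climb exhausts the path the record is counted
   and excluded from the output rather than guessed at. In practice the
   top path element (a domain name) resolves, so this is rare and
   always reported.

Homonyms (one name, several taxa) are resolved deterministically:
scientific-name bindings outrank other classes; among equally ranked
bindings the smallest taxon ID wins and a warning is logged. Duplicate
accessions in the export keep the last occurrence, with a warning,
since the mapping file needs unique keys. Merged/deleted-taxon dump
files are not consulted.

## Read binning

Input is standard 12-column BLAST tabular output (chosen because it is
bit-exact and ubiquitous; pairwise-format parsing is out of scope).
Multiple HSPs to the same accession are collapsed to the best bit score
so one reference sequence cannot vote twice. Thresholds, with units and
defaults:

| parameter   | default | meaning |
|-------------|---------|---------|
| Min Score   | 120 bits | hits below are ignored; reads with no surviving hit are *unassigned-low-score* |
| Top Percent | 10 %     | retain hits with `bit_score >= best * (1 - p/100)` among Min-Score survivors |
| Min Support | 5 reads  | taxa attracting fewer reads have them pushed to the parent |

Min Score is applied to the **bit** score (a `--min-score` flag allows
other values; raw-score thresholds can be emulated by scaling). The Top
Percent band is relative to the best *surviving* hit, so the best hit
always survives. The read is assigned to the LCA of the taxa its
retained, mappable accessions resolve to; reads whose retained
accessions are all absent from the mapping are *unmapped-accession*
(tracked as its own bin so that assigned + no-hits + low-score +
unmapped always equals the reads processed).

Min Support is implemented as a push-up, not a discard: nodes are
processed deepest-first in a single sweep, each under-supported node's
reads moving to its parent, with counts re-examined as pushed reads
arrive (a parent that becomes under-supported after absorbing children
is pushed in its own turn). The root retains whatever reaches it.
Deepest-first processing makes the sweep equal to the naive
repeat-until-stable oracle while staying O(nodes) per profile. Profiles
can afterwards be collapsed at a named rank (genus by default);
counts on taxa with no ancestor of that rank stay on their own node so
totals are conserved.

Two monotonicity properties follow from these definitions and are
asserted in the test suite: raising Min Score never increases the
assigned count, and widening the Top Percent band never deepens an
assignment (the LCA over a superset is an ancestor-or-self of the LCA
over the subset).

## Profile comparison

External classifiers often export flat genus/abundance CSV tables
(headerless, two columns). These are imported through the same name
index and homonym rule; genera that do not resolve accumulate in a
no-hits bin rather than being dropped silently. Flat sources place all
mass directly on genus nodes — no hierarchy is inferred for them.

The comparison table covers the ancestor-closure of every taxon
observed in any profile, ordered by a depth-first traversal of the
taxonomy (children visited in taxon-ID order). Each sample contributes
a raw column and a *summarized* column (reads on the node plus its
entire subtree), satisfying `summarized[t] = raw[t] + Σ
summarized[children(t)]` at every row, with the root row equal to the
column total. Counts are emitted raw; normalization across methods with
different totals is left to the user, since no single convention fits
all six-way comparisons.

## Synthetic data generator

The fixtures module emulates the three inputs at desk scale:

* **Taxonomy** — a random tree over the canonical rank ladder
  (superkingdom → species), ~200 taxa by default, with 30 % of taxa
  receiving synonym/equivalent/misspelling records, 5 % of those being
  deliberate homonyms, and one `environmental samples` pseudo-genus to
  exercise the path-keyword skip.
* **SILVA export** — 500 accessions attached to random species; 20 %
  get blocked `uncultured …`-style full names (their truth is the
  deepest resolvable path element), 10 % get case-mangled names
  (exercising the retry), 5 % are fabricated records that exist nowhere
  in the taxonomy (truth: unmapped).
* **BLAST table** — 2000 reads; each read's top hit is its true source
  accession with a bit score uniform in [150, 400]; 30 % of reads get
  1–3 decoy hits at 60–98 % of the top score; 5 % score entirely below
  120 (truth: unassigned-low-score) and 5 % hit only undatabased
  accessions (truth: unmapped-accession). Bit scores are drawn
  uniformly — only threshold behavior matters here, so no attempt is
  made at realistic BLAST score modeling.

Default sizes (200/500/2000) keep every property suite comfortably in
single-digit seconds while still exercising homonyms, blocked names and
all read statuses simultaneously. Each generator draws from its own
stream seeded by `(seed, generator-name)`, so outputs are byte-stable
and adding a generator never perturbs existing fixtures.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequence-level alignment effects
(chimeras, partial 16S fragments, correlated bit scores between related
references), the real SILVA taxonomy's disagreements with NCBI's, and
real `names.dmp` quirks such as merged or deleted taxa. The pipeline's
correctness on those inputs rests on the dialect parsers being faithful,
not on the simulation.

## Numerical and degenerate-input choices

* Ties in hit scores: dedup keeps the best HSP per accession; the Top
  Percent band uses `>=`, so tied-at-threshold hits are retained.
* `lca` of a singleton is the element itself; unknown IDs raise with
  the offending ID named.
* Empty inputs are values, not errors: an empty names file parses to an
  empty record list, an empty BLAST file to a zero-read profile, an
  empty mapping to an empty file that round-trips.
* All parsers report malformed input as `file:line: message`.
* Mapping files are written accession-sorted, so identical inputs give
  byte-identical outputs.

## Known limitations

* Merged (`merged.dmp`) and deleted (`delnodes.dmp`) taxa are not
  consulted; a mapping built from mismatched names/nodes versions can
  reference taxa the tree lacks (the binner raises, naming the
  accession).
* RDP "Assignment detail" and SILVA-website log formats are not parsed;
  external results enter only as genus/abundance CSV.
* The tool consumes BLAST output; it never runs BLAST.
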