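# silvamap

Taxonomic analysis of 16S rRNA amplicon reads from BLASTN-vs-SILVA
output, against the NCBI taxonomy.

SILVA, the curated rRNA reference database, identifies its sequences by
accession and by a taxonomic path — not by NCBI taxon IDs. A BLAST hit
list against SILVA therefore cannot be placed on the NCBI taxonomy
directly. `silvamap` closes that gap for microbiome researchers in two
steps:

1. **Mapping file construction.** Each record of a SILVA ARB "NDS field
   export" (accession, taxonomic path, full organism name) is resolved
   against a hash map built over *all* NCBI name classes (scientific
   names, synonyms, equivalent names, misspellings, from `names.dmp`).
   A usable full name resolves directly; names containing `uncultured`,
   `unidentified` or `metagenome` instead trigger a climb of the
   taxonomic path from its lowest element upward (skipping elements
   containing `environmental samples`); names that merely miss are
   retried with changed capitalization. The result is a two-column
   accession → taxon-ID "synonym" file.

2. **LCA binning.** Reads in 12-column BLAST tabular output are
   assigned to NCBI taxa: hits below **Min Score** (120 bits) are
   discarded; among the survivors only those within **Top Percent**
   (10 %) of the best bit score are kept; their accessions are
   translated through the mapping file and the read is placed on the
   lowest common ancestor of the resulting taxa. Finally **Min
   Support** (5 reads) pushes counts on weakly supported taxa up to
   their parents, giving a conservative profile. Profiles — including
   flat genus/abundance CSVs from external classifiers — can be merged
   into a side-by-side comparison table with per-node subtree totals.

## Worked example

All inputs can be synthesized with recorded ground truth — no database
downloads are needed:

```
silvamap make-fixtures --out fx/ --seed 5 --n-taxa 100 --n-accessions 80 --n-reads 200
silvamap build-mapping --names fx/names.dmp --silva fx/silva_export.tsv --out mapping.tsv
silvamap assign --blast fx/blast_hits.tsv --mapping mapping.tsv \
    --names fx/names.dmp --nodes fx/nodes.dmp --out profile.tsv
silvamap compare --profile profile.tsv --names fx/names.dmp --nodes fx/nodes.dmp --out comparison.tsv
```

The `build-mapping` step reports, on stderr:

```
mapped 77/80 accessions (capitalization retry=4, full-name match=52, path match=21, unmapped=3) -> mapping.tsv
```

i.e. 52 records resolved by their full organism name, 21 via the
taxonomic-path climb (blocked `uncultured`-style names), 4 after a
capitalization retry, and 3 — records fabricated to exist nowhere in
the taxonomy — stayed unmapped and were excluded from the file. The
`assign` step then prints:

```
blast_hits: 200 reads (assigned=185, no-hits=0, low-score=9, unmapped=6) -> profile.tsv
```

185 reads were placed on a taxon; 9 never reached the Min Score of
120; 6 hit only accessions absent from the mapping file. The profile
TSV lists taxa (collapsed at genus rank) with their read counts, and
`comparison.tsv` adds, per sample, a *summarized* column: reads on the
node or anywhere in its subtree.

As a concrete mapping trace: the record
`AB365303 | Eukaryota; …; Turbinidae; Homalopoma | Homalopoma granuliferum`
maps by full name to taxon 336503, while
`AY548990 | Bacteria; …; Family XII Incertae Sedis; Fusibacter | uncultured bacterium`
has a blocked full name and climbs its path to *Fusibacter* (76008).

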