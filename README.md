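# proteogut

Lineage-aware gene-prediction consensus, non-redundant protein cataloguing,
and protein-ecology statistics for gut metagenomes — as one offline,
desk-scale Python toolkit.

What it does:

- **Taxonomic routing** (`proteogut.taxonomy`): contigs are routed from
  Kraken-style taxon assignments (or a plain contig/taxid table) to a
  (domain, genetic code) prediction group via a flat rule table with parent
  links; host contigs are excluded; unclassified contigs take the
  bacteria-default route with translation table 11 but keep the distinct
  `Unknown` domain label.
- **Genetic codes and ORF scanning** (`proteogut.codes`): NCBI translation
  tables 1, 4, and 11 shipped as a plain-text data file; code-aware
  translation (ambiguity codons → `X`) and a deterministic six-frame ORF
  scanner that reports the longest start per stop (minimum length 21 nt =
  six amino acids plus the stop codon).
- **Consensus merge** (`proteogut.merge`): multi-tool predictions grouped by
  strand + 3′ terminus; longest start wins per group, distinct stops all
  retained; edge-partial (start codon in the first/last three contig bases)
  and sub-minimum-length genes removed; survivors translated with the
  routed code, internal-stop translations discarded. Proteins are named
  `index|dataset|domain|table|tool1[-tool2[-tool3]]`.
- **Catalogue** (`proteogut.catalogue`): greedy longest-first clustering at
  90 % identity / 80 % shortest-sequence coverage (identity = identical
  columns / alignment columns of a local alignment), with a lossless exact
  4-mer prefilter and a brute-force reference implementation; singleton and
  small-protein-cluster (≤50 aa representative) flags; directed catalogue
  overlap by co-clustering; permutation rarefaction curves.
- **Ecology** (`proteogut.ecology`): query-vs-corpus search at 90/90/90
  identity/query-coverage/subject-coverage (or a precomputed BLAST outfmt-6
  table); per-metadata-group prevalence with a log-space two-sided Fisher
  exact test and Benjamini–Hochberg correction per metadata variable;
  multi-protein intersection mode; function-positive fraction from a
  genome×individual abundance matrix; taxonomic range per cluster.
- **Expression** (`proteogut.expression`): aligned read fraction, RPKM, and
  expression prevalence per cluster from best-hit read alignment tables.
- **Evaluation** (`proteogut.evaluation`): perfect/partial/missed/spurious
  scoring of tools and k-tool combinations against a reference annotation.
- **Synthetic fixtures** (`proteogut.synthetic`): seeded generators for
  contigs with planted genes (including engineered same-stop start
  conflicts, edge-partials, short genes, and valid decoys), simulated tool
  outputs with miss/start-shift/spurious error models, protein families
  with exact substitution budgets, metadata/abundance fixtures with planted
  odds ratios, and read-count tables — so no download is ever required.

## CLI

```sh
proteogut simulate --preset merge --seed 1 --out fx/    # seeded fixture + truth
proteogut predict  --contigs fx/contigs.fa --table 11 --min-len 21
proteogut merge    --contigs fx/contigs.fa --taxa fx/assignments.tsv \
                   --preds fx/toolA.gff3 --preds fx/toolB.gff3 \
                   --dataset demo --out out/
proteogut cluster  --proteins out/demo.proteins.faa --id 0.9 --cov 0.8
proteogut investigate -s query.faa --corpus out/demo.proteins.faa \
                   --metadata meta.tsv
proteogut evaluate --ref fx/truth.gff3 --preds fx/toolA.gff3 \
                   --preds fx/toolB.gff3 -k 2
proteogut express  --alignments s1.tsv --total-reads 1000000 \
                   --clusters clusters.tsv --rep-lengths lengths.tsv
```

Supported formats: FASTA, GFF3, a six-column tabular prediction dialect
(contig/start/end/strand/frame/score), Kraken-style classification output,
two-column contig/taxid TSV, BLAST/DIAMOND outfmt-6 hit tables, and TSV
metadata/abundance matrices.

## Notes on fixed conventions

- Coordinates are 1-based inclusive on the forward strand; for `-` strand
  features `start <= end` still holds and the start codon occupies
  positions `end-2..end`.
- Pairwise identity/coverage definitions are fixed in `proteogut.align`
  (local alignment, match +1 / mismatch −1 / gap −1).
- Tool tokens must not contain `|` or `-`; both are reserved separators of
  the protein naming scheme. Multi-tool credit in a name is restricted to
  tools whose predictions had identical coordinates.
- "Expressed" means ≥1 mapped read (configurable); cluster RPKM uses the
  representative's length.
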