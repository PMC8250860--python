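# stalkscan

Trait-association pan-genomics for microbial genome sets.

Given a collection of annotated genomes (GFF3 + protein FASTA pairs) and a
table assigning each genome to a morphological trait group, stalkscan:

* builds **pan-genomes** at a sweep of minimum protein identity thresholds
  (partial-sequence filtering, greedy pre-clustering, all-vs-all
  similarity graph, Markov clustering at inflation 1.5), with
  core / accessory / strain-specific partitions, gene accumulation curves
  over random genome orderings and a Heaps-law openness exponent;
* screens for **trait-unique gene families** — present in every
  trait-positive genome, absent from every trait-negative genome — across
  the threshold sweep, with a >70% mutual-coverage check that flags (but
  keeps) families containing split-gene fragments, and a follow-up
  **distant-homolog search** below the clustering threshold;
* detects **syntenic cassettes** of trait-unique genes (contiguous runs
  with a configurable gap tolerance) and tests gene-order conservation
  across genomes up to full reversal, reporting fragmented cassettes and
  flanking-gene neighborhoods;
* computes **AAI** (average amino-acid identity over reciprocal best hits,
  30% identity / 70% coverage defaults), Bray-Curtis profile
  dissimilarity, average-linkage (UPGMA) dendrograms in Newick, and
  species-rank groups at AAI > 95%;
* scans proteins for short **conserved motifs** (c-di-GMP binding RxxD /
  RxxxR, glycosyltransferase QxxRW / DxD / TED), builds center-star MSAs
  and counts identical columns;
* tests **COG category enrichment** per pan-genome subdivision
  (two-sided Fisher exact + Benjamini-Hochberg);
* generates seeded **synthetic communities** with a machine-readable
  truth ledger — core/accessory/strain-specific structure, a planted
  trait-linked syntenic cluster, an adjacent conserved neighbor cassette,
  near-miss decoy families, optional sub-40%-identity homologs in
  "dread" negatives and an optional split-gene artifact — used as the
  test oracle for every pipeline stage.

All pairwise comparisons run through one deterministic affine-gap
overlap-alignment kernel (BLOSUM62, gap open 11 / extend 1, free terminal
gaps, pinned tie-breaking), numba-compiled.

## CLI

```sh
# generate a 16-genome synthetic community with truth ledger
stalkscan simulate --seed 42 --out community/

# full analysis: sweep + screen + synteny + AAI + motifs + COGs
stalkscan run-all --genomes community/genomes --traits community/traits.tsv \
    --cogs community/cogs.tsv --out results/

# or with a YAML config (thresholds, union range, seeds, cutoffs)
stalkscan run-all --config pipeline.yaml

# individual stages
stalkscan pangenome --genomes community/genomes --out results/ --threshold 50
stalkscan aai       --genomes community/genomes --out results/
stalkscan traitscan --genomes community/genomes --traits community/traits.tsv --out results/
stalkscan synteny   --genomes community/genomes --traits community/traits.tsv --out synteny.tsv
stalkscan motifs    community/genomes/S01.faa --out motifs.tsv
stalkscan cogs      --genomes community/genomes --traits community/traits.tsv \
                    --cogs community/cogs.tsv --out cog_enrichment.tsv
```

`run-all` writes per-threshold presence/absence CSVs and trait-unique
reports, a union report, accumulation curve TSV, Heaps fit JSON, AAI
matrix + Newick tree, synteny and motif TSVs, COG enrichment TSV, a
top-level `summary.json` and a `MANIFEST` of completed stages. Logs go to
stderr; machine output goes to files only.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes independent oracles (exhaustive alignment enumeration,
pure-python MCL iteration, O(n^3) UPGMA, hypergeometric Fisher
enumeration, a naive motif matcher and an exhaustive 3-way alignment DP)
plus property tests. `tests/test_acceptance.py` holds the binding
acceptance criteria; the full run takes ~7 minutes on one CPU (dominated
by a 20-seed planted-cluster recovery check).

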