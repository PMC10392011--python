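# olfrep

Annotation and comparative analysis of fish chemoreceptor gene repertoires.

Ray-finned fishes smell through four unrelated receptor gene families —
odorant receptors (OR), trace-amine-associated receptors (TAAR), and the
two vomeronasal families (V1R, V2R), jointly called OLF genes. Repertoire
sizes vary by nearly two orders of magnitude between species, the genes sit
in dense tandem clusters, and repertoire size covaries with ecology
(freshwater, amphibious, nocturnal lineages) and with the cellular
processing capacity of the olfactory bulb (OB). `olfrep` implements the
full computational chain needed to study this system, for people who work
on gene-family evolution in non-model genomes:

1. **simulate** — seeded generation of multi-scaffold genomes with planted
   receptor clusters (family-specific lengths, divergence, strands,
   introns, pseudogenes, decoy GPCRs), Dirichlet/multinomial expression
   counts with ambiguous read classes, and Brownian trait/count/brain-cell
   panels on ultrametric pure-birth trees — ground truth for every stage.
2. **annotate** — iterative translated homology search (six-frame
   seed-and-extend, BLOSUM62), best-hit overlap resolution, HSP chaining
   with family intron caps (10 kb OR/TAAR/V1R, 30 kb V2R), 3 kb region
   extension, ORF recovery with the 275 aa / 700 aa intact-length filters,
   and decoy-aware family/subtype classification; assembly QC (N50 ratio,
   BUSCO floors, OR scaffold dispersion).
3. **clusters** — tandem cluster calling under the self-referential gap
   rule (largest intergenic gap ≤ cluster span / 3), pairwise sequence
   identity (PSI) matrices in genomic order, greedy identity grouping,
   and cross-species cluster homology via flanking synteny anchors.
4. **expression** — EM rescue of ambiguously mapped reads, co-receptor
   exclusion, replicate-averaged relative abundances, genomic-versus-
   transcriptomic family proportions, the expression-concentration
   statistic (fraction of receptors holding half of all OLF expression),
   per-cluster accumulated/average expression (AcEx/AvEx), and
   reads-per-million tissue comparisons.
5. **comparative** — Brownian covariance from a time-calibrated Newick
   tree, phylogenetic generalized least squares (PGLS; REML by default),
   the OB cellularity model
   `log10(OB cells) ~ log10(rest-of-brain cells) + log10(OLF genes)`,
   FAN (freshwater + amphibious + nocturnal) classification, and group
   contrasts on log10 gene counts.

## Worked example

Run the whole chain on a compact synthetic genome:

```bash
olfrep run --config demo.yaml
```

with `demo.yaml`:

```yaml
seed: 7
outdir: demo
simulate:
  n_scaffolds: 2
  scaffold_length: 250000
  clusters_per_scaffold: 2
  genes_per_cluster: [5, 6]
  decoy_count: 4
  seq_depth: 50000
  n_species: 16
```

The manifest (`demo/manifest.json`) reports, among others:

```json
"annotate": {
 "iterations": 2,
 "family_counts": {"OR": 13, "TAAR": 5, "V1R": 0, "V2R": 0},
 "recovery": {"sensitivity": 1.0, "precision": 1.0,
              "intact_calls_at_pseudogene_loci": 0}
},
"clusters": {"n_clusters": 5, "largest_cluster_size": 5},
"expression": {"expression_concentration": 0.2222, "acex_total": 100.0},
"comparative": {"n_species": 16, "n_fan": 4, "ob_olf_p": 0.983}
```

Reading this: all 18 planted intact receptors were recovered with no false
positives and none of the planted pseudogenes were called intact; the
intact models group into 5 tandem clusters; about 22% of receptors account
for half of the simulated olfactory-organ expression, and per-cluster AcEx
sums to 100% as it must; 4 of 16 species fall in the FAN clade. The OB
cellularity coefficient is not significant here — a 16-species panel has
little power at the generator's modest effect size; the calibration
benchmarks below quantify this properly at n = 32.

Per-stage outputs land next to the manifest: `genome.fa`, `truth.gff3`,
`models.gff3`, `proteins.fa`, `clusters.bed/json`,
`psi_largest_cluster.tsv`, `abundance.tsv`, `cluster_expression.tsv`,
`ob_residuals.tsv`, `comparative_fits.json`.

Each stage is also a library call (`olfrep.iterate_annotation`,
`olfrep.call_clusters`, `olfrep.pgls`, ...) and a CLI subcommand
(`olfrep annotate --genome g.fa --refs refs/ --out dir/`, etc.).

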