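# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `olfrep`, in the order the pipeline runs them.

## Synthetic data generator (`olfrep.simulate`)

The generator exists so that every downstream stage can be tested against
known truth without any external download. One `SimConfig` (including its
seed) fully determines every output byte.

**References.** Each receptor family gets a random base protein; templates
within a family sit at ~10% divergence from the base. Independent random
bases put inter-family identity near the alignment noise floor (well under
the 40% used as a sanity check), which mimics the fact that OR, TAAR, V1R
and V2R are unrelated GPCR families. OR templates carry subtype labels
(γ among them) so subtype classification via labelled references can be
exercised. A fifth, decoy family stands in for non-olfactory GPCRs in the
classification database. Template lengths are 320 aa (OR/TAAR/V1R) and
750 aa (V2R) so intact planted genes clear the 275/700 aa length filters
with slack.

**Genomes.** Clusters are family-homogeneous (tandem duplication produces
runs of related paralogs). Each planted gene is a point-mutated copy of a
family template at the configured amino acid divergence (default 0.30),
reverse-translated with uniform, seeded synonymous-codon choice, on a
random strand, separated from its neighbours by 200–1500 bp. Adjacent
clusters sit tens of kb apart so truth clustering is unambiguous under the
gap rule. With probability `tandem_dup_prob` a gene is instead a ~1%
diverged copy of its neighbour — the "recent duplicate" case that creates
read-mapping ambiguity. Pseudogenes (an exact count, `rate × n genes`)
carry a premature stop at 30–60% of the CDS, placed so that neither
fragment passes the intact-length filter. Introns (GT…AG, 0.2–2 kb, at a
codon boundary) appear with probability `intron_prob` in V2R genes and a
fifth of that elsewhere, matching the V2R bias of real multi-exon
receptors. An in-frame stop codon is planted immediately 5' of every start
codon so the true ORF start is well defined. Decoy genes are overwritten
into free background ≥ 5 kb from any receptor.

Not modelled (out of scope by design): sequencing reads and their error
profiles, indel-rich pseudogene decay, repeats, GC heterogeneity. Passing
recovery tests therefore demonstrates correctness of the annotation logic,
not robustness to assembly artefacts.

**Expression.** True proportions are symmetric Dirichlet(α = 0.8): this
concentration makes the expression-concentration statistic fall around
15–20% for repertoires of ~100 genes, the empirically observed range for
olfactory epithelia. Replicates (default two, the usual design) are
multinomial draws at `seq_depth`. Every gene pair at ≥ 97% protein
identity (edit-distance screen) contributes a shared ambiguity class
holding a binomial `ambig_fraction` of each member's reads; classes are
pairwise only — enough to exercise the EM, higher-order sharing is out of
scope.

**Comparative panel.** Pure-birth trees (dendropy) with terminal branches
extended by 5% of the depth — a tree stopped exactly at a speciation event
has zero-length terminal branches and a singular Brownian covariance —
then rescaled to unit depth. A random clade covering 20–40% of tips
carries the FAN phenotype; placing the trait on a clade rather than
i.i.d. across tips is what makes phylogenetic and ordinary regression
genuinely differ. log10 gene counts = 2.35 + BM(σ² = 0.09) + β·FAN with
β = 0.5: σ² gives ≈ 0.3 sd on the log10 scale (the observed spread of fish
repertoires around a median of ~220 genes) and β approximates the observed
FAN fold-difference. log10 OB cells = −2 + log10(rest-of-brain cells) +
γ·log10(counts) + N(0, 0.05²), γ = 0.2. Note the OB noise is i.i.d., not
Brownian, so the PGLS fitted to panel data is mildly misspecified — this
is deliberate (real residuals are not exactly Brownian either); the
calibration benchmarks that need exact nulls generate residuals from the
Brownian covariance directly.

## Annotation (`olfrep.annotate`)

**Search.** Six-frame translation of each scaffold; exact 4-aa word seeds
against all reference proteins; two seeds on the same diagonal within
40 aa trigger an ungapped BLOSUM62 X-drop extension (X = 25) that never
crosses a stop codon. HSPs with raw score ≥ 120 are reported. Raw score
thresholds replace e-values: on desk-scale databases e-values are
meaningless, and the empirical null (1000 random scaffolds) shows zero
HSPs at this threshold. Extension is ungapped; the full affine-gap
dynamic-programming aligner used everywhere else in the package serves as
the scoring cross-check in the tests. An externally produced tabular hit
file (BLAST outfmt 6 plus a strand column) can be dropped in instead of
the built-in search.

**Overlap resolution.** HSPs on one scaffold and strand form connected
components under interval overlap; within a component only the query with
the highest summed score survives (ties to the lexicographically smaller
query id). This is the deterministic reading of "keep the best hit".

**Chaining.** HSPs of one (query, scaffold, strand), in genomic order,
chain when the gap is at most the family intron cap (10 kb OR/TAAR/V1R,
30 kb V2R) *and at least 50 bp*, and query coordinates advance
collinearly (up to 15 aa of query overlap is tolerated, since ungapped
extensions overrun exon boundaries by a few residues). The 50 bp floor is
load-bearing: without it, the two HSP fragments flanking a premature stop
codon chain across a 3 bp "intron" and resurrect pseudogenes as intact
models. Real introns are never that short.

**ORF recovery.** The draft region is extracted with 3 kb flanks
(clamped at scaffold edges). Single-exon drafts take the longest ATG→stop
ORF on the model strand that overlaps the homology segment — anchoring to
the draft stops a longer ORF from a neighbouring cluster gene inside the
flank from hijacking the model. Multi-exon drafts are spliced at HSP
boundaries after trimming query-overlapping residues, outer exons are
extended in frame to the nearest stop codons, and the longest ORF inside
the spliced translation is kept. Proteins shorter than 275 aa
(OR/TAAR/V1R) or 700 aa (V2R) are rejected; the boundaries are inclusive
(275 and 700 pass). Because junction trimming cannot always tell which
side of an exon boundary the overrun came from, a recovered multi-exon
protein can differ from the truth by a residue or two at the junction;
single-exon proteins are recovered exactly.

**Classification.** Global alignment (BLOSUM62, affine 11/1) against the
initial reference database including decoys; the best-scoring reference
assigns family and subtype. Rejections: best hit is a decoy (`non_olf`),
best score < 150 (`low_score`), or identity to the best non-decoy
reference < 35% (`low_identity` — the folded-in stand-in for an external
model optimizer's identity floor; identity is identical columns over
alignment columns, terminal gaps excluded).

**Iteration.** Accepted models join the *search* reference set (the
classification database stays fixed) and the whole chain repeats until an
iteration adds no new model or `max_iter` (default 5; in practice the
benchmark genomes converge in 2) is reached. Model identity is keyed on
the genomic interval (scaffold, start, end, strand), not the protein, to
avoid oscillation between near-identical sequences. This recovers genes
reachable only through intermediate homologs, as the two-hop test
demonstrates.

**Assembly QC.** Three filters: N50 / genome length ≥ 10 Mb per Gb
(boundary inclusive); BUSCO completeness ≥ 90%, relaxed to 85% for
Polypteriformes; intact OR models on fewer than 20 scaffolds, up to 30
allowed for lineages with a whole-genome duplication.

## Cluster calling (`olfrep.clusters`)

A cluster is valid when its largest intergenic gap is at most one third of
its genomic span (span = last gene end − first gene start; singletons are
valid clusters of size 1, filtered only at display time with the
five-gene threshold). The rule is self-referential — the allowed gap grows
with the span — and prescribes no construction order, so the caller
agglomerates: start from singletons, repeatedly merge the adjacent pair
with the smallest inter-cluster gap whose merged block is still valid
(ties to the leftmost pair), stop at the fixed point. This is
deterministic, translation-invariant, and verified against an independent
exhaustive oracle on 1000 random instances. Intergenic distance ignores
strand (real clusters mix strands).

PSI matrices use the same global aligner; identity is identical columns
over alignment columns with terminal gap columns excluded. Identity
grouping is greedy longest-first: each sequence joins the first existing
representative it matches at or above the threshold. Cluster homology
across species is anchor-set intersection on the supplied flanking
ortholog groups; a cluster matching two or more partners is flagged as a
rearrangement split. Anchors are inputs — whole-genome synteny inference
is out of scope.

## Expression (`olfrep.expression`)

EM treats each ambiguity class as reads from a mixture of its member
transcripts: the E-step splits a class proportionally to current
abundances, the M-step re-estimates abundances from expected counts;
iteration stops when the abundance vector moves < 1e-8 in sup-norm
(non-convergence returns the last iterate with a flag). Expected counts
conserve the input total exactly and the likelihood is non-decreasing. No
transcript-length normalization is applied — receptors within a family are
nearly equal length, so this deliberately diverges from TPM semantics.

Relative abundance normalizes within each replicate and averages the
fractions across replicates (renormalizing the mean to guard rounding);
pooling raw counts first is available behind the replicate table for
sensitivity analysis. Known co-expressed co-receptor genes are removed
before normalization. The concentration statistic sorts abundances
descending and returns k*/N for the smallest k* whose cumulative share
reaches 0.5, boundary inclusive; it is ceil(N/2)/N under uniformity and
never exceeds 0.5 + 1/N. AcEx is a cluster's percent of total expression,
AvEx its per-gene average; with every expressed gene mapped to exactly one
cluster (singletons included) AcEx sums to 100. Tissue comparisons use
counts per million within each library.

## Comparative statistics (`olfrep.comparative`)

The Brownian covariance of a time-calibrated tree has C_ij = depth of the
MRCA of tips i and j, C_ii = tip depth. PGLS estimates
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y via Cholesky whitening; the residual rate σ̂² is
REML (residual sum of whitened squares over n − p) by default, ML
optional — both are exposed because either convention is defensible and
they differ only in σ̂². Standard errors come from σ̂²(XᵀC⁻¹X)⁻¹ and
two-sided p-values from the t distribution with n − p degrees of freedom.
With C = I the fit reproduces ordinary least squares to 1e-8 (verified
against statsmodels), and results are invariant to covariance scaling and
tip order. A ridge of 1e-10·trace is added only if Cholesky fails. Pagel's
λ is not fitted; the covariance is pure Brownian.

The OB cellularity model regresses log10 OB cells on log10 rest-of-brain
cells and log10 OLF gene count (all variables log10-transformed); the
residual table for plotting comes from the two-covariate base model.
Species with missing data or absent from the tree are dropped and
reported. FAN classification requires salinity = freshwater, amphibious,
and activity = nocturnal; species with unknown activity are excluded and
reported, and the arrhythmic class is treated as non-nocturnal in
contrasts (excluded from the nocturnal/diurnal splits of the group
summaries). Group contrasts are PGLS of log10 counts on a binary
indicator, per family or on the total.

Bayesian multilevel trait models (MCMC) are out of scope; PGLS contrasts
are the trait-effect surface of this package.

## Benchmark problem sizes

The recovery benchmark plants 90 receptors (80 intact, 10 pseudogenes,
exact counts) in 10 clusters of 9 on five 400 kb scaffolds, plus 20
decoys, at 30% divergence — 2 Mb of genome, annotated in seconds. PGLS
calibration uses 1000 Brownian simulations at n = 32 on one fixed tree
(coverage and type-I error) and the first 500 null fits for the KS
uniformity check. The determinism check runs the full pipeline twice on a
150 kb single-scaffold configuration. These sizes keep the whole suite
and the acceptance script comfortably within a desk-scale run while
leaving every statistical check adequately powered.

## Known limitations

- Ungapped HSP extension: genes with indel divergence from all references
  would be chained from fragmented HSPs and may lose terminal residues;
  the simulator does not generate indel divergence, so this path is
  untested against truth.
- Multi-exon protein recovery can be off by a residue or two at splice
  junctions (see ORF recovery above).
- Identity from one optimal alignment: co-optimal alignments can differ
  in identity by fractions of a percent; scores are unique and are what
  thresholds act on.
- E-value semantics, repeat masking and spliced-alignment modelling beyond
  HSP-boundary splicing are deliberately absent.
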