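# Methods

This note documents the models and procedures implemented in `lincscan`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not establish.

## Identification cascade

Candidate transcripts (assembled models, GTF) pass through six ordered
filters. Every removal is recorded with a reason in a `FilterReport` whose
invariants (each stage's survivors are a subset of the previous stage's;
survivors plus removals partition the input) are checked after every run.

1. **Length** — spliced length ≥ `min_length` (default 200 bp, the standard
   lncRNA definition boundary; 199 bp is removed, 200 bp kept).
2. **Intergenic position** — the transcript's genomic span must not
   intersect any protein-coding gene interval expanded by `flank_bp`
   (default 500 bp) on both sides. Intersection is strand-blind half-open
   interval overlap: a transcript antisense-overlapping a gene is *not*
   intergenic, matching the usual lincRNA definition. Transcripts on
   chromosomes absent from the annotation are removed as `unplaced` with a
   warning. The flank guards against unannotated extended exons of
   neighboring genes.
3. **Coding potential** — the mean hexamer log-likelihood ratio
   (coding vs noncoding model) over the longest ORF, read in frame at step
   3; if no ORF exists, over the whole sequence in frame +1. Transcripts
   scoring > 0 are removed (the score-zero boundary is kept exactly:
   a score of 0 is noncoding). Externally produced coding-ID lists, when
   supplied, are unioned with the internal classifier's calls.
4. **ORF length** — longest ORF across all six frames must be
   < `orf_max` = 100 amino acids (stop codon excluded; 99 aa kept, 100 aa
   removed). Six frames are scanned because most single-exon assembled
   transcripts are unstranded; this is conservative (removes more). Codons
   containing N never match start or stop.
5. **Housekeeping similarity** — any hit against the housekeeping-RNA
   database (tRNA/rRNA/miRNA-style sequences) at E ≤ `hk_evalue` = 1e-5
   removes the candidate; the threshold is inclusive. Either a FASTA
   (searched with the built-in aligner) or imported 12-column tabular hits
   can be supplied.
6. **Redundancy clustering** — greedy incremental clustering, longest
   sequence first (ties: ID ascending). A sequence joins the first cluster
   whose representative it matches at ≥ `cluster_identity` = 0.95, where
   identity = matching positions of the best local alignment divided by the
   *shorter* sequence length. The shorter-sequence denominator makes
   containment duplicates (truncated re-assemblies) collapse; the longest
   member represents the cluster. Ties everywhere resolve by length
   descending then ID ascending, so outputs are reproducible.

The hexamer tables are fixed and shipped: the coding model treats an
in-frame hexamer as a codon pair under a positionally biased codon-usage
table (with stop codons down-weighted to keep the model strictly positive),
the noncoding model is a product of mildly AT-rich base frequencies. The
synthetic generator draws its coding ORFs from the same codon table, so
classifier and generator share one generative story. This replaces external
coding-potential classifiers with a single implemented score while keeping
their decision rule (eliminate score > 0).

## Homology search and conservation

`local_align` is a word-seeded, ungapped local aligner: exact `word_size`
(default 11) seeds located through a subject k-mer index, extended in both
directions with X-drop termination (default 20), scored +1/match, −2/
mismatch. E-values use the Karlin–Altschul formula E = K·m·n·exp(−λS) with
the published ungapped parameters for +1/−2 (λ = 1.28, K = 0.46). Hits are
kept at E ≤ 1e-5 and identity ≥ 0.20 (a permissive floor, applied per hit
over its aligned length). Both subject strands are searched. Extension is
ungapped by design: the package's mutation model is substitution-only, and
gapped alignment is out of scope. A lincRNA counts as conserved in a
species when ≥ 1 hit survives; the all-species set is the intersection.

## Expression profiling

- *Expressed*: max FPKM over samples ≥ `min_fpkm` = 1 (inclusive).
- *τ*: computed on per-tissue mean raw FPKM by default; a `log2p1` scale is
  available since the index's upstream preprocessing varies between
  studies. τ is scale-invariant, 0 ≤ τ ≤ 1, undefined (error) for all-zero
  vectors or fewer than two tissues. Tissue-specific means τ strictly
  > 0.95, assigned to the argmax tissue.
- *Stage calls*: expressed in a stage iff max FPKM over the stage's samples
  ≥ 1; stage-specific when exactly one stage qualifies.
- *Settlement contrast*: on in stage A, off in stage B means max FPKM
  ≥ `hi_fpkm` = 5 ("moderate and high") in A and < 1 in B; reported
  symmetrically for both directions.
- *Distribution comparison*: Gaussian KDE with Silverman bandwidth on
  log2(FPKM+1), plus the two-sample Kolmogorov–Smirnov statistic with the
  asymptotic p-value (the quantity of interest is a p-value floor, so
  exact small-sample corrections are immaterial).
- *Neighbors*: distance is the gap between closest interval ends (0 for
  overlap); lincRNAs within 10 kb of a protein-coding gene define the
  neighbor-gene set passed to enrichment.

## Co-expression network

Gene–gene correlation defaults to Pearson on log2(FPKM+1) (the weighted
network convention); trait correlations are Spearman throughout, since
development trends are monotone but non-linear. The network is unsigned by
default (A = |cor|^β); a signed variant is available. β is the smallest
power in 1..20 whose connectivity histogram fits a power law with R² ≥ 0.8
over ≥ 8 occupied log-log bins, falling back to 6 with a warning — the
fallback is the documented default for matrices with no scale-free regime
(e.g. white noise).

Topological overlap uses the standard formula with self-adjacency excluded
from connectivity; TOM is symmetric with entries in [0,1] and is checked
against an O(n³) oracle in the tests. Modules come from average-linkage
hierarchical clustering on 1−TOM with a **static** cut at height 0.25 and
a minimum size of 10; clusters below the size floor join the grey
unassigned pool. A static cut was chosen over the dynamic recursive cut
because it is deterministic, directly testable, and sufficient for
planted-block recovery; the height default matches the within-module TOM
dissimilarity the generator produces at its default noise. Module labels
follow the conventional color sequence by size rank (cosmetic only).

Eigengenes are the first principal component of the standardized member
submatrix, unit norm, sign-oriented to correlate non-negatively with the
members' mean profile. A module is trait-related when |Spearman ρ| ≥ 0.6
and p < 0.01 against any development trait (days, time-order rank, stage
ordinal). Per-gene trait correlations are BH-adjusted *within each module*
(per-module significant counts are the reported quantity; a global-FDR mode
exists). Hubs are the top ⌈hub_percentile·|module|⌉ members by intramodular
connectivity kIM = Σ same-module adjacency, ties by ID. "Directly
connected" lincRNAs are those sharing one of the module's
`edge_export_top_k` (default 100) strongest edges with a hub — an
operationalization chosen because exported co-expression networks are
necessarily edge-thresholded.

## Enrichment

One upper-tail hypergeometric test per term with ≥ 1 hit in the gene set
(scipy's log-space survival function; verified against exact rational
enumeration for all populations N ≤ 30). Bonferroni multiplies by the
number of terms actually tested; both raw (p < 0.05) and corrected columns
are emitted rather than choosing one. No GO-graph ancestor propagation is
performed: the term map is taken as given. Default backgrounds: all
annotated protein-coding genes for neighbor analysis, all matrix features
for modules; both overridable.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` packs onto one chromosome (default 4 Mb): 200 coding
genes (ORFs of 150–300 aa drawn from the shipped codon model, short UTRs),
50 planted lincRNAs (250–800 bp, intergenic with > 500 bp clearance,
longest ORF < 100 aa, coding score ≤ 0, no housekeeping hit — all verified
at generation with the same oracles the pipeline uses, re-drawn otherwise),
and six decoy classes of 10: sub-200 bp transcripts, transcripts inside
genes, transcripts in gene flanks, intergenic long-ORF transcripts (ORF
≥ 100 aa with noncoding hexamer composition, so they pass the coding score
and fall at the ORF stage), near-duplicates (a 90% prefix of a planted
lincRNA mutated at 2%, identity ≥ 0.95 verified), and housekeeping
look-alikes (mutated database entries). Intergenic gaps are mostly 1–7 kb
with occasional 13–29 kb deserts so nearest-neighbor distances straddle
the 10 kb window. A small fraction of lincRNAs get two exons; the rest are
single-exon, matching the heavily single-exon character of assembled
lincRNA catalogs. Four subject genomes carry 2%-mutated copies of ten
lincRNAs (all four genomes) plus ten more in one genome each, half
reverse-complemented.

`simulate_expression` produces a nine-tissue matrix (tissue-specific
lincRNAs: log-normal high FPKM in one tissue — male gonad favored, as in
testis-dominated specificity patterns — and < 0.5 elsewhere, τ > 0.95
checked at generation; broad features: per-feature log-normal baseline with
τ < 0.5 checked) and a 34-time-point development matrix with six stages
(embryo → spat). Module members follow strictly monotone sigmoid
eigen-profiles with staggered transition points — monotone so the Spearman
correlation with time rank is exactly ±1, staggered so cross-module Pearson
correlations stay low enough for module separation — plus Gaussian noise
(default SD 0.3 on log2 FPKM; the designated hub gets 0.08, near-hub
members 1.25×, the designated hub-linked lincRNA 1.5× that). Stage-specific
lincRNAs are ≥ 5 FPKM in all samples of one stage and < 1 elsewhere; the
settlement sets are on in the pediveliger (or spat) side of the boundary
and off on the other, with a second "on" stage so they are not
single-stage. Because single-stage lincRNAs of the two contrasted stages
also satisfy the settlement contrast by definition, the truth table's
expected contrast sets include them. Stage-specific planting is weighted
toward the terminal sessile stage, mirroring the juvenile-dominant pattern
seen in real oyster development panels.

All randomness flows from one integer seed through a single generator;
fixed seed means byte-identical FASTA/GTF/TSV outputs.

**Limitations.** The generator does not simulate reads, splice-isoform
complexity, indels, GC-biased coverage, or correlated noise between
features; decoys violate exactly one filter each, whereas real false
positives can be marginal on several axes at once. Passing recovery tests
therefore demonstrates correctness of the implemented logic and thresholds
under the stated generative model, not performance on real libraries.
Problem sizes (hundreds of features, 34 samples, ~60 kb subject genomes)
were chosen so the full test suite and the acceptance script each run in
minutes on one CPU; the algorithms are O(n²)–O(n³) in features and are not
block-wise, so matrices beyond ~20k features are out of scope.

## Numerical choices

- ORF ties across frames resolve to the first frame in +1,+2,+3,−1,−2,−3.
- The coding score includes the stop codon's hexamer; with no ORF the
  fallback window is the whole sequence, frame +1, stepping 3.
- Correlation matrices are clipped to [−1,1]; constant features correlate 0
  with everything (warned).
- Scale-free R² is an ordinary least-squares fit of log10 p(k) on log10 k.
- Eigengene sign: non-negative correlation with the members' mean
  standardized profile; flipping all members leaves the oriented eigengene
  unchanged.
- Hypergeometric arguments are validated (0 ≤ k ≤ min(n,K) ≤ N); k = 0
  returns exactly 1.
- The E-value threshold (≤), FPKM threshold (≥), length threshold (≥), ORF
  threshold (< max), identity threshold (≥) and τ threshold (>) boundaries
  are each pinned by a dedicated test.
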