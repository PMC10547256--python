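# Methods

`zfte` is a desk-scale re-implementation of the computational evidence for
coevolution between tandem C2H2 zinc-finger (ZNF) genes and transposable
elements (TEs): a genome census of tandem-ZNF and retroelement ORFs,
phylogenetically corrected copy-number correlation, binding-motif enrichment
in TE sequences, site-level selection at DNA-contacting finger residues, and
knockdown-derepression expression statistics.  Every stage runs on synthetic
inputs with planted ground truth, so the whole study is testable without
external downloads.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Statistical primitives (`zfte.stats`)

All tests the pipeline uses are implemented in-package with exact
small-sample behaviour: Fisher's exact test by hypergeometric enumeration
(two-sided rule: sum of table probabilities at most the observed, with a
1e-7 relative slack for floating-point ties, matching common reference
implementations), one-tailed binomial tails summed in log space (p-values
down to ~1e-300 are representable), Wilcoxon rank-sum with exact
enumeration for pooled n <= 12 and a tie/continuity-corrected normal
approximation above, Spearman's rho on mid-ranks with exact permutation
p-values for n <= 9 and the t-approximation above, Benjamini–Hochberg
step-up for every "q-value"/FDR in the pipeline, and Shannon entropy in
bits.  A constant vector passed to the rank correlation raises
`ConstantInputError` rather than silently returning 0; a fully tied
Wilcoxon returns p = 1 with a flag.

Choices: "FDR" and "q-value" always mean BH (order-free and reproducible);
Fisher tests are one-sided wherever the analysis states a direction
(enrichment, derepression) and two-sided otherwise.

## Synthetic data (`zfte.sim`)

The generators define the study conditions; all are pure functions of a
config including its seed.

* **Genomes** (`simulate_genome`): i.i.d. uniform background with stop
  codons sprinkled on both strands (default 0.02/bp) so long stop-free
  background stretches are rare.  Planted ORFs are `stop|ATG..codons|stop`
  constructs on either strand: ZNF ORFs encode k tandem `C-x2-C-x12-H-x3-H`
  repeats with 5–10-residue spacers and chosen helix contact residues
  (-1/+2/+3/+6 sit at indices 5/7/8/11 of the 12-mer); retroelement ORFs
  carry an RT (YxDD-box) or RNase-H catalytic core.  Filler residues
  exclude C/H (and D) so domain patterns anchor only where planted and the
  census recovers planted ORFs at exactly their recorded coordinates.
* **Trait trees** (`simulate_trait_tree`): Yule topologies scaled to unit
  depth, bivariate Brownian motion with correlation rho from root to tips
  (the |rho| = 1 case handled exactly).  A pectinate "caterpillar" option
  provides the strongly imbalanced topology on which naive cross-species
  correlations are anticonservative.
* **TE/background libraries** (`simulate_te_libraries`): random sequences
  with a motif consensus planted at a random position/strand in a set
  fraction of TE sequences; the background library reuses the exact length
  multiset and is rejection-sampled so the motif (either strand) never
  occurs in it.
* **Codon alignments** (`simulate_codon_alignment`): per-site Gillespie
  simulation along the tree under an MG94-style scheme — single-nucleotide
  codon changes at a base rate, x kappa for transitions, x omega(site) for
  nonsynonymous changes, stop codons forbidden; rates are normalised so a
  neutral site's expected substitution rate is 1 per unit branch length,
  so omega > 1 sites genuinely evolve faster.
* **Expression experiments** (`simulate_expression_experiment`): features
  are genes plus TE families with stage-trajectory templates (maternal /
  early-peak at the minor ZGA wave / late-peak / flat) scaled to a
  lognormal expression level; counts are negative-binomial (dispersion
  0.1).  The knockdown arm plants log2 fold changes of +1.5 (young TE
  families), +0.3 (old), and a symmetric ±1.2 on 15% of genes — the
  experiment this emulates saw on the order of a thousand directly
  perturbed genes, and without gene-level DE the kind-by-direction Fisher
  table would be structurally degenerate.  Young families get insertion
  divergences < 0.01 substitutions/site, old families above.  Transcript
  exon structures, TE insertion tables and −30..+25 start-codon windows
  (40% containing the morpholino's reverse complement) are emitted for the
  length, age and MO analyses.  `truth.expected_stage_mu` records the
  noiseless mean trajectories.

What the generators do **not** emulate: sequencing reads, alignment and
counting noise beyond NB sampling, batch effects, indels and realistic TE
sequence evolution, genome GC structure.  Passing tests therefore show the
analysis machinery is correct and calibrated under its stated model, not
that it is robust to artefacts of real pipelines.

## Domain census (`zfte.census`)

ORFs are ATG-to-stop, maximal per stop-free stretch, in all six frames,
retained at 375–10,000 nt (stop excluded); codons containing N translate to
X and never start or stop an ORF; coordinates are 0-based half-open on the
forward strand with strand recorded separately.  Domain detection is
deterministic regex scoring — C2H2 `C.{2,4}C.{12}H.{3,5}H`, plus short
catalytic-core stand-ins for RT and RNase-H shipped with their Pfam
accessions as metadata — resolved leftmost-longest.  Hits within 100
residues group into one array for reporting; grouping never reduces the
domain count, and an ORF enters the ZNF census only with >= 5 total C2H2
hits.  Retroelement ORFs need a single RT or RNase-H hit.  Assemblies below
a 50 kb scaffold N50 are dropped, and the census reports a QC Spearman
correlation between ZNF count and N50 across retained assemblies.

## Independent contrasts (`zfte.phylo`)

One representative per taxonomic family (largest scaffold N50; ties to the
lexicographically smallest assembly id — the family-choice rule is this
package's own convention).  Traits are log10(count + 1) before contrasting;
polytomies are resolved deterministically (sorted-label order) with
zero-length internal branches, and zero branches get epsilon = 1e-8 x tree
depth.  Felsenstein pruning: contrast (x_i - x_j)/sqrt(v_i + v_j),
precision-weighted ancestral value, parent branch extended by
v_i v_j/(v_i + v_j).

Contrast pairs have arbitrary orientation, so the test statistic uses the
standard positivization (flip each pair so the x-contrast is >= 0) before
Spearman.  Folding a bivariate normal attenuates its correlation
(Pearson_folded = rho sqrt(1-2/pi)/sqrt(1-rho^2 2/pi), ~0.63 of nominal at
rho = 0.8), so positivized rho is a test statistic, not an estimate of
rho; magnitude recovery is checked on signed contrasts (`positivize=False`),
which average ~0.79 for simulated rho = 0.8 — the Spearman value of a
rho = 0.8 bivariate normal.  Both are reported by the pipeline.

## Motif enrichment (`zfte.motifs`)

Binding motifs come from a fixed recognition-code table (package data
`recognition_code.tsv`) mapping (helix position in {-1,+2,+3,+6}, residue)
to base preferences; unknown residues fall back to uniform 0.25.  Each
finger yields a 3-bp block — 5' base from +6, middle from +3, 3' from the
renormalised elementwise product of -1 and +2 (folding the +2 cross-strand
contact into the 3' column) — and blocks concatenate in reverse finger
order, the C-terminal finger binding the 5'-most triplet.  The table's
content is a plausible, editable stand-in; synthetic proteins are
constructed so the table predicts the planted motif, making all tests
closed under it.

Scanning scores log-odds against a uniform (overridable) background.
Exact p-values come from a DP convolution of per-column score
distributions discretized at 1/1000 of the motif's score range; columns
are rounded at step/width so the summed rounding drift stays within half a
step, the scanner sums the same integer column scores the DP uses
(p-value lookup is exactly consistent), and `pwm_exact_pvalue` lowers its
integer threshold by the worst-case drift so every truly passing word is
counted — the reported tail is within one granularity step of exact.
BH q-values are computed per motif–library pair over all scanned positions
(both strands); a sequence is "matched" iff any position has q < alpha
(default 0.05), and a motif *set* counts a sequence once.  Enrichment is a
one-tailed binomial test of x matched TE sequences out of n at a baseline
p0 taken from the matched background library or from the shuffled motif
(column permutation with an enforced derangement); a zero baseline with
x > 0 is flagged as degenerate rather than divided through.  Motif
similarity is best ungapped alignment over offsets/orientations scored by
mean per-column Pearson correlation with a seeded column-permutation null;
the cross-species comparison is a one-sided Fisher test on motif–TE pairs
(the counting unit is this package's choice; the original analysis does
not state its unit).

## Selection analysis (`zfte.selection`)

Global protein alignment is affine-gap Needleman–Wunsch (BLOSUM62, open 10,
extend 0.5, gap cost open + extend x length, deterministic
diagonal-then-up-then-left traceback), distance = 1 - identity over
non-gap-gap columns (the original toolchain's metric is unstated; identity
is the simplest defensible choice).  Neighbor joining is Saitou–Nei with
lexicographic tie-breaks in Q and negative branch lengths clamped to zero
with the deficit moved to the sibling; additive matrices are reproduced
exactly.  Clade selection takes maximal single-species clades with >= 10
members and length spread <= 30 aa.  Codon alignments are built by
back-threading CDS through the protein alignment and dropping any column
containing a gap.

dN/dS is Nei–Gojobori (1986) counting: per-codon synonymous site fractions
exclude changes to stop codons from the denominator; multi-step codon
differences average over all stop-free orderings of the differing
positions (uniform weights; verified against exhaustive pathway
enumeration for all 61x61 sense-codon pairs); Jukes–Cantor correction with
a saturation flag at p >= 3/4.  The site profile sums pathway-averaged
Nd/Sd and site counts over all sequence pairs per codon column; site
omega = (Nd/N)/(Sd/S), with the alignment-wide mean Sd/S as the dS
denominator when a site has no synonymous change (so nonsynonymous-only
sites get a large finite omega instead of dividing by zero), and
no-difference sites flagged undefined.  Contact enrichment is a one-sided
Fisher test of (contact vs non-contact) x (omega > 1 vs <= 1) over
defined-omega sites, with contact sites located from the C2H2 anchors.
This counting profile plus the enrichment test replaces maximum-likelihood
site models, which are out of scope here.  The entropy profile maps
domains onto a canonical 25-position coordinate system anchored at the
C,C,H,H residues (variable spacers left-aligned and padded to maximal
span) and reports Shannon entropy and coverage per position.

## Expression and knockdown (`zfte.expression`)

Effective lengths: genes take the median over transcripts of the
union-of-exon length (even counts: mean of the middle two); TE families sum
all insertion lengths.  TPM is rate = count/length scaled to 1e6.  Waves:
unexpressed if the trajectory never reaches 0.5 TPM; maternal if expressed
at the egg stage; else early when the TPM peak precedes the major ZGA
stage, late otherwise.  Applied to noiseless expected trajectories the rule
recovers planted templates exactly; on NB-noisy single-library counts about
1% of expressed features flip (2-sigma count draws combined with TPM's
compositional denominator), which bounds what wave labels on real
single-replicate series can promise.  TE peak timing is average-linkage
hierarchical clustering of z-scored trajectories cut at k = 2, clusters
labelled by mean peak position relative to the collection (shield) stage;
constant trajectories are assigned by argmax directly.

Differential expression is a minimal NB Wald test: median-of-ratios library
normalisation, per-feature moment dispersions shrunk 50/50 in log space
toward an alpha(mu) = a0 + a1/mu trend, delta-method standard error of the
log2 fold change, standard-normal reference, BH q-values.  The normal
reference was chosen after measuring both calibration and power at the
study conditions (3 vs 3 replicates, dispersion 0.1): null DE call rate
~0.5–1.3% at the FDR 0.05 + |log2FC| >= 0.32 thresholds, power ~0.99 for a
planted log2FC of 2 at mean 100; a t(4) reference is so conservative it
destroys power.  DE calls: up/down at q < 0.05 and |log2FC| >= 0.32.

The knockdown summary emits, with empty strata as NA rows: Fisher
(one-sided) of up/down by kind (TE vs gene), overall and per TE class;
one-sided Wilcoxon of log2 fold changes, young vs old (median insertion
divergence < 0.01 splits the classes; ties at exactly 0.01 are old) overall
and per class; per-category binomial tests of at-least-x up-regulated among
DE features at p0 = 0.5; and a before/after peak-timing Wilcoxon.  MO
target counting requires an exact (0-mismatch) occurrence of the
morpholino's reverse complement in the transcript's −30..+25 sense window —
the window span is this package's convention.  Gene age uses terminal
branch lengths on a gene tree with a one-sided Wilcoxon (maternal older).

## Orchestration, determinism and problem sizes

`zfte.pipeline` runs generate → census → correlate → enrich → select →
express from one flat config in which every threshold above appears once
with its default.  Unknown keys are rejected.  Each stage writes TSV/JSON
outputs plus a manifest (sha256 of inputs and outputs, parameters, seed,
package version); reruns at a fixed seed are byte-identical.  The default
demo sizes — 3 assemblies of 2 x 50 kb contigs, 60 trait-tree taxa, 60 TE
sequences, a 10-taxon/8-finger selection alignment, 150 genes + 60 TE
families x 3 replicates — complete in a few seconds on one core; the
recovery/calibration studies in the test suite use 20–50 seeded replicates
per property and a few minutes in total.  These sizes are the package's
chosen desk-scale study conditions; all thresholds (375/10,000 nt, >= 5
domains, 100-residue merge, 50 kb N50, alpha 0.05, FDR 0.05, |log2FC| >=
0.32, 0.5 TPM, 0.01 substitutions/site) are the study's values and are not
tuned per run.

## Known limitations

Regex domain scoring has no notion of profile-HMM bit scores, so remote
homologs of real domains would be missed; the recognition-code table is a
stand-in, not a trained predictor; NG86 counting is less powerful than ML
site models for weak selection; the NB Wald test is minimal (no GLM
covariates, no outlier handling); wave classification is rule-based on TPM
trajectories and inherits their compositional artefacts; and all
calibration statements hold under the generators' models, not under real
sequencing noise.
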