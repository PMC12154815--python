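# Methods

## Scope and data flow

`guqtl` analyses *cis* genetic effects on immunoglobulin light-chain gene
usage. Inputs are (a) a multi-sample VCF of biallelic SNVs and SV deletions
with phased GT, (b) per-individual personalized germline allele sets
(FASTA + diploid allele table), (c) AIRR Rearrangement TSVs per sample, and
(d) a locus annotation BED (V/J exons, introns, L-Part1, RSS heptamer /
spacer / nonamer, gene bodies), optionally plus a TFBS-cluster BED. Stages:
repertoire preparation → usage matrix → LD structure → guQTL scan →
networks → CDR3 property QTLs → allele linkage / enrichment. Every stage is
a plain library function; the CLI and `pipeline.py` only wire files
between them.

## Repertoire preparation

Allele calls are first restricted to each individual's personalized
germline set (as happens naturally when alignment uses a personalized
database); paralog collapsing runs afterwards, because ambi labels do not
exist in germline sets. IGK proximal/distal paralogs whose allele sequences
are cohort-wide inseparable are always rewritten to a fixed ambi label
(IGKV1-33, 1-37, 1-39, 2-28, 2-40 pairs; the IGLJ2/IGLJ3 cassette genes
collapse to IGLJ2-3ambi). Configurable pairs (defaults IGKV1-12/1D-12,
1-13/1D-13, 6-21/6D-21) stay distinct only for individuals in whom every
proximal allele sequence differs from every distal allele sequence; the
per-individual disambiguation status is recorded, and genes analysable only
in a disambiguated subcohort are scanned over that subcohort.
Multi-assignment calls (comma-separated) are kept when all members resolve
to one label after mapping, otherwise dropped and counted — the choice is
logged because no single convention is standard.

The unmutated/mutated partition is exact: unmutated ⇔ V identity = 1.0 and
J identity = 1.0 (AIRR fractional convention; a percent converter is
provided). Samples with fewer than 100 unique sequences are removed.

## Usage matrix

Usage counts at the gene level (allele suffix after `*` ignored) over
unique sequences, one column per sample; frequencies are counts over the
sample's total unique sequences, computed before gene filtering and not
renormalized afterwards, so retained-gene columns may sum to < 1. Genes are
retained when their count reaches 10 in at least one sample. Unmutated and
mutated matrices are computed independently from their partitions.

## Association scan

Each gene×variant pair is fitted by simple OLS on dosage with the two-sided
t test (df = n−2) and adjusted R². The fit is closed-form (centered
cross-products) and vectorized across the full gene×variant grid; samples
missing a phenotype are handled pairwise per test. Usage is regressed
untransformed — no logit or rank normalization by default — and no
covariates are included (a hook exists, but the default model is
intercept + dosage only).

Multiple testing: variants with identical information (genotype r² exactly
1, i.e. affinely dependent dosage vectors) collapse to one effective test;
the per-gene threshold is α / (number of perfect-LD groups among tested
variants), shared by all genes in the locus. Perfect-LD grouping
canonicalizes each centered dosage vector by its first non-zero entry, so
the equivalence is exact for integer dosages, including 2−x mirrors.

Lead variants are the minimum-P significant tests, ties broken by larger
|β| then smaller position, with all co-minimal variants reported (perfect-
LD leads arrive as groups). Variant location uses the precedence coding >
intron > L-Part1 > RSS subfield > intergenic; fold change is the ratio of
homozygote-group mean usages, falling back (flagged) to the extreme
genotype-class means when a homozygote class is absent, undefined on a zero
minimum. SV genotypes are reported on the diploid copy-number scale; the
additive check tabulates mean usage per copy number with a monotonicity
flag.

## LD structure

Genotype r² is the squared Pearson correlation of diploid dosage vectors
with pairwise-complete samples. Haplotype frequencies come from direct
counting when GT is phased and otherwise from EM over double-heterozygote
phase ambiguity (tolerance 1e-8, ≤ 1000 iterations). D′ = D/D_max with the
classical normalization; its 90% CI evaluates the multinomial likelihood of
the haplotype counts on a |D′| grid of step 0.001 (allele frequencies at
their MLEs, sign of D fixed), normalizes, and reads the 0.05/0.95
cumulative points. Gabriel classification: strong LD iff CI low ≥ 0.70 and
CI high ≥ 0.98; strong recombination iff CI high < 0.90; a candidate
interval is a block iff its outermost pair is strong-LD and ≥ 95% of
informative pairs inside are strong-LD. Maximal non-overlapping blocks are
taken greedily, longest span first, ties to the leftmost. The
block-size-dependent minimum-informative-pair refinements used by some
implementations are deliberately not applied: the canonical rule keeps
block recovery analytically predictable on planted fixtures. Block-gene
overlap is ≥ 1 bp interval intersection on 1-based inclusive coordinates
(BED input is converted from 0-based half-open).

## Networks

Genes with ≥ 1 significant variant are nodes; pairs with a non-empty
intersection of significant sets get an edge weighted by the shared count
and the Jaccard index. Maximal cliques are enumerated exactly
(Bron–Kerbosch with pivoting via networkx) — gene counts are small enough
that heuristics are unnecessary — and connected components are reported
alongside. Graph layout is presentation-only and untested.

## CDR3 properties

The junction spans the conserved C through the conserved F/W; CDR3 is the
junction minus those two residues (junctions shorter than 2 trim to empty
and are excluded from means, counted). Per-sequence descriptors: length;
GRAVY (mean Kyte–Doolittle hydropathy); mean Zimmerman bulkiness; mean
Grantham polarity; aliphatic index (nA + 2.9·nV + 3.9·(nI+nL))/len;
aromatic fraction over {F, W, H, Y} (an {F, W, Y} alternative is switchable);
basic {R, H, K} and acidic {D, E} fractions; and net side-chain charge by
Henderson–Hasselbalch at pH 7.4 with the EMBOSS pK table, termini excluded
— pH, pK table and aromatic set are configuration because conventions
differ between toolkits. Scales ship as an editable JSON asset. Sample
means are unweighted over unique sequences; the property-QTL scan reuses
the OLS machinery with the same per-locus effective-test Bonferroni
denominator (not further divided by the number of properties). Gene-subset
means restrict to sequences calling one V gene, for attributing a
locus-wide property shift to specific genes.

## Allele linkage and enrichment

For each gene with a significant lead, a table of diploid allele-copy
counts (2 per individual; carrier percentages reported separately) by lead
genotype class is tested with Fisher's exact test: closed-form
hypergeometric for 2×2 (one- or two-sided), exact enumeration over all
fixed-margin tables for r×c (two-sided, probability-ordering convention),
switching to Monte-Carlo permutation sampling (≥ 1e5 draws, fixed seed,
reported SE) when the table space exceeds 1e6. Copy counting was chosen
over carrier counting as the tested unit; both are computed. Genes with
cohort major-allele frequency > 95% classify as `no_variation`; otherwise
the Bonferroni-corrected Fisher result splits `varies_with_guQTL` from
`varies_independent`. TFBS enrichment is the one-sided 2×2 test of
{guQTL, non-guQTL} × {overlapping, non-overlapping}; a track covering the
whole locus has no contrast and reports P = 1.

## Synthetic cohorts

The generator emulates the inputs, not any particular population: block
haplotype pools are drawn whole per chromosome (no within-block
recombination or mutation) and blocks assort independently, which makes
Gabriel-block recovery analytically predictable; SV deletion alleles are
independent Bernoulli per haplotype. Gene propensities follow
w = exp(μ_g + Σβx + ε)·Π(cn/2) with ε ~ N(0, σ_g²), usage is the softmax
across genes, and each sequence draws its gene categorically, its
chromosome uniformly (reporting that chromosome's allele name), its mutated
flag Bernoulli(π_mut) with identity 0.97 on one random segment (any value
< 1 triggers the partition rule), and its junction as C + 3-residue
germline V suffix + 0–4 random inserted residues (alphabet excludes C so
inserts never mimic the conserved cysteine) + 2-residue J prefix + F.
Genes with coding effects or explicit allele linkage get a second allele
riding on the alt haplotype. One RNG stream per run with per-individual
sub-seeds keeps bundles byte-identical for a fixed seed.

Defaults: per-sample unique sequences uniform on 1,000–5,000 (the scale of
real per-sample repertoires at tractable cost), σ_g = 0.2, π_mut = 0.5 —
values chosen once as realistic study conditions. The generator does not
model somatic hypermutation at sequence level, UMI/read noise, clonal
structure or heavy-chain pairing, so passing tests demonstrate correctness
of the statistical machinery on model-faithful data, not robustness to
those real-data complications.

A note on compositionality: because usage frequencies sum to 1 per sample,
a variant that raises some genes necessarily depresses the others, so
non-driven genes acquire genuine negative associations with planted
variants. This mirrors real repertoire data and is why planted-clique
checks assert that the driven genes are contained together in a maximal
clique rather than that the clique contains nothing else.

## Validation experiments and sizes

`guqtl.experiments` fixes the validation conditions: null calibration with
2,000 replicate genes × 50 independent common variants at n = 200;
planted-effect recovery with 20 genes (MAF 0.3, β = 1) over 50 seeds at
n = 200; Gabriel recovery of two 4-variant blocks over 100 seeds at
n = 500; and one end-to-end cohort at n = 150 planting a stop-codon
suppressor, an additive SV deletion, a pleiotropic 5-gene block and an
aromatic-rich V suffix. These sizes were chosen as the smallest at which
each effect is comfortably identified; `scripts/acceptance.py` re-runs all
of them from a single seed.

## Known limitations

- Unphased-input D′ relies on EM haplotype frequencies; borderline Gabriel
  pair classes can differ from tools with other CI estimators, so block
  boundaries near the thresholds are implementation-sensitive.
- No conditional/secondary QTL analysis and no trans-locus effects.
- No covariate adjustment by default (ancestry, age, sex); results on
  structured cohorts need the covariate hook or upstream stratification.
- The r×c exact test enumerates tables; very large sparse tables fall back
  to Monte Carlo with a reported SE rather than an exact value.
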