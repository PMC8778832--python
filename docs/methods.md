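# Methods

This note records the statistical conventions cubkit implements, the
choices made where several defensible variants exist, and what the
synthetic data generator does and does not emulate.

## Sequence model and scope

The unit of analysis is an in-frame coding sequence (CDS) over
A/C/G/T (U is normalized to T on input; all reports print RNA-alphabet
codons, the convention of published codon-usage tables). The genetic
code is fixed to the standard nuclear code. For ambisense circular
genomes with two major ORFs, the helper `concatenate_orf12` builds the
conventional analysis unit: replicase ORF minus its stop codon followed
by capsid ORF minus its start codon. A flag permits non-standard
boundaries because one PCV species has an unresolved replicase 5'
boundary; the exact coordinates used in published datasets are not
recoverable, so the flag only disables checking, it does not guess.

Deduplication removes sequences with 100% identity of the exact
normalized nucleotide string, keeping the first occurrence. Per-ORF
deduplication is deliberately not attempted: identity is defined on the
analysis unit.

## Degeneracy classes and the 59-codon space

Synonymous statistics run over the 18 amino acids with degenerate
families; Met, Trp and stops are excluded everywhere. Leu, Ser and Arg
are treated as single six-codon families — the CodonW convention —
rather than split into their sub-boxes. The resulting classes are
9 two-fold, 1 three-fold (Ile), 5 four-fold and 3 six-fold families,
59 codons in all. RSCU matrices use a fixed documented column order
(amino acids in the standard codon-table row order, codons alphabetical
within a family) so PCA loadings are comparable across runs.

## Composition conventions

Two third-position variants are computed and both are emitted:

* **A3s/C3s/G3s/U3s and GC3s** over synonymous codons only (excluding
  AUG, UGG, stops). These sum to 100% and are the CodonW-style "s"
  quantities; they feed the PR2 coordinates and the ENC-plot abscissa.
* **GC1/GC2/GC3** over all codons, with GC12 = (GC1+GC2)/2.

The neutrality plot defaults to the all-codon GC3/GC12 pair
(`gc3_mode="all"`), switchable to GC3s. Published per-species tables do
not always state which variant they print; making both available keeps
either reading reproducible. A CDS consisting only of AUG/UGG codons
has undefined synonymous third-position frequencies; these are reported
as NaN with an explicit flag, never as zero.

## ENC

Wright's estimator in the form used by CodonW: per family with total
count N ≥ 2, homozygosity F = (N·Σp̂² − 1)/(N − 1); class means over
the families observed; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped
at 61. An empty Ile class is replaced by the mean of the two- and
four-fold class means; any other empty class raises an error naming the
classes, since no principled substitution exists. A warning is issued
below 100 codons, where the estimator is noisy. The expected-ENC null
curve is ENC(s) = 2 + s + 29/(s² + (1−s)²); some renderings of this
formula omit the division, but only the quotient form has the correct
extremes (61 region at s = 0.5, 31 at s = 0), which is what the
implementation and its tests pin.

## CAI and reference tables

CAI is the Sharp–Li geometric mean of relative adaptiveness weights
over the 59 synonymous codons. Reference tables may be given as raw
counts, frequencies per thousand, or precomputed RSCU; all are
normalized to per-family RSCU and then to weights w = RSCU/max(RSCU)
per family, so each family's best codon has w = 1 exactly. Zero or
missing codons within a covered family receive w = 0.01 (the smallest
positive weight convention) so the log-score stays finite; a family
entirely absent from the source table is imputed as neutral (w = 1 for
all its codons, contributing nothing to the log mean) and logged. Both
floors are configurable.

## Codon classification

Preferred = per-family RSCU argmax; over-represented = RSCU > 1.6 and
under-represented = RSCU < 0.6, both strict, so boundary values are in
neither set. Ties at the argmax (realistic at the 2-decimal precision
of published tables) are broken toward the codon with higher RSCU in a
supplied reference table, else alphabetically; the reference tie-break
reproduces the published preferred-codon listings for the bundled PCV
profiles.

## Mutation–selection diagnostics

PR2 coordinates are A3/(A3+U3) and G3/(G3+C3) from the synonymous
third-position frequencies; a 0/0 coordinate is flagged undefined.

The neutrality regression is ordinary least squares of GC12 on GC3
(reduced major axis is available as an option but the regression line
drawn in this literature is OLS). Points are screened for outliers
first; the default rule is Tukey fences (1.5 × IQR applied to GC3 and
GC12 marginally, a point removed if outside either fence), with
"3 × SD" and "none" selectable, every removal logged. The published
analyses mention outlier removal without stating a rule, so the rule is
configurable rather than asserted. Both Pearson and Spearman
correlations of the kept points are reported, since published neutrality
plots do not always name the correlation type.

The contribution split is mutation % = min(|slope|, 1)·100 and
selection % = 100 − mutation %. This identity is not usually printed
but is forced by every published slope/contribution pair this package
reproduces, and is adopted as the definition; it clips at |slope| = 1
so the percentages stay in [0, 100] and always sum to exactly 100.

The correlation matrix is Spearman's rank rho (average ranks for ties)
for each pair in (A3s, C3s, U3s, G3s, GC3, ENC) × (A%, C%, U%, G%, GC%,
Gravy, Aroma), with significance stars at p < 0.05 (*) and p < 0.01
(**), two-sided.

Group comparisons of CAI use all pairwise two-sided Mann–Whitney tests
(exact where scipy chooses exact), unadjusted by default since the
study design this mirrors reports no correction; Benjamini–Hochberg is
available as a flag. The compact letter display is built by
insert-and-absorb over the significance graph, with groups ordered by
descending mean.

## PCA

PCA of the sequences × 59 RSCU matrix, mean-centered without variance
scaling: RSCU values share a common scale by construction, so unit
variance scaling would up-weight near-constant codons (a scaling flag
exists). Families a sequence never uses have undefined RSCU and are
imputed at the neutral value 1.0 with a flag; this keeps the 59-space
complete without pushing the point in any bias direction. Component
signs are fixed so the largest-magnitude loading of each PC is
positive, making scores deterministic across solvers; the
implementation is cross-checked in tests against a raw
eigendecomposition of the covariance matrix.

## Synthetic data

The generator emulates codon-composition structure only: it draws amino
acids i.i.d. from a composition vector and codons i.i.d. from per-family
probability vectors. It does not emulate phylogenetic correlation,
substitution processes, recombination, length variation or positional
dependence along a gene — so passing tests demonstrate correctness of
the statistics, not realism of any evolutionary claim. Defaults are
300 codons per sequence and 20 sequences per population, the scale of
the small circovirus ORF12 datasets (roughly 540 codons per sequence,
tens of strains for the rarer species).

`biased_usage` tilts each family's mean codon probability in proportion
to gc3_target for G/C-ending codons and 1 − gc3_target otherwise, then
draws the family vector from a Dirichlet with that mean; the
concentration parameter (total Dirichlet alpha) sets between-family
variability. At target 0.5 the mean is exactly uniform for every
family; at other targets the family-level synonymous GC3 is exact for
the 17 families with balanced third-base classes and deviates only for
Ile (two A/U-ending codons against one G/C-ending), shifting the
18-family average by well under 0.01.

`generate_neutrality_set` embeds a linear GC12–GC3 relationship
exactly, by construction rather than by rejection: it restricts the
amino-acid alphabet to families whose first two codon positions are
entirely A/U (Phe, Ile, Tyr, Asn, Lys) or entirely G/C (Pro, Ala, Gly),
so GC12 is set by an amino-acid quota and GC3 independently by a
third-base quota; both measured values match their targets to within
1/(2·length) ≈ 0.0017 at the default 300 codons. Such sequences use no
six-fold families, so ENC is undefined for them — the metrics table
records NaN — which is irrelevant to their purpose (the neutrality
regression uses only composition). Start/stop wrapping is omitted here
so measured composition equals the constructed targets.

All generators take one explicit integer seed, use a single local
numpy Generator, and are byte-deterministic; FASTA headers carry a
short hash of the generating spec as provenance.

## Problem sizes in the validation suite

The test and acceptance runs use deliberately modest sizes chosen to
make the targeted effects unambiguous at comfortable margins: 500
sequences for neutrality-slope recovery (tolerance ±0.05 at noise SD
0.005), 50 × 500-codon sequences for GC3 target recovery (±0.02), 2 ×
20 sequences for two-population PC1 separation, and ~1.8 million codons
for RSCU convergence of the generator (max deviation < 0.05). These are
the package's reference validation conditions, fixed independently of
any particular run's outcome.

## Known limitations

* Only the standard nuclear genetic code; no alternative codes.
* ENC follows the CodonW variant; other tools (e.g. DnaSP, coRdon)
  differ in rare-family handling and can disagree by a few units on
  short sequences.
* Recombination screening, ORF calling from full genomes and GenBank
  retrieval are out of scope; the pipeline entry point is a FASTA of
  assembled coding sequences.
* The mutation/selection "contribution" is the conventional slope
  reading of the neutrality plot, a descriptive decomposition — not a
  causal estimate, and no substitute for dN/dS-style selection tests.
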