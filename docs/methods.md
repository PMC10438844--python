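# Methods

This note records the models implemented in `encapmap`, their assumptions,
the defaults and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genetic model of the backcross

A cross of F₁ heterozygotes to the susceptible parent produces progeny
that are heterozygous (HET) or homozygous-susceptible (HOM_S) at every
autosomal locus, each with marginal probability ½. Genotypes along a
chromosome are modelled as a two-state Markov chain whose transition
probability between loci at map distance *d* cM is the Haldane
recombination fraction

    r(d) = (1 − e^(−2d/100)) / 2.

Haldane (no crossover interference) was chosen over Kosambi because it is
exactly consistent with the Markov-chain construction — the composition of
two Haldane transitions over adjacent intervals equals the Haldane
transition over their union — so simulation and inference share one model.

The phenotype (melanization of the wasp egg) is Bernoulli with penetrance
p_het for heterozygotes and p_hom for homozygotes at a single causal
locus. Survival equals the phenotype (susceptible flies are killed by the
parasitoid); an optional genotype-independent background survival rate
(default 1) can thin the cohort without changing the genotype-conditional
structure.

## Interval mapping of a binary trait

At each grid position (default step 0.5 cM, union of the grid with the
marker positions) the HET probability per individual is computed from the
nearest non-missing flanking markers; by the Markov property this
conditioning is exact, and missing markers are marginalised by skipping to
the next informative one. The likelihood

    L₁ = Π_i [ w_i f(y_i; p_het) + (1 − w_i) f(y_i; p_hom) ]

is maximised by EM over the hidden genotype (monotone; analytic M-step;
tolerance 1e−8 on the log-likelihood, at most 500 iterations; probabilities
clipped at 1e−9 for stability). LOD compares L₁ with the genotype-free
binomial fit. Peak ties break toward the smaller cM value. The support
interval is the contiguous region around the peak where LOD ≥ peak − drop
(default 1.5), with the endpoints linearly interpolated between grid
points; a flat scan returns the full span with a warning flag.

Composite interval mapping uses a logistic model: phenotype regressed on
the position's HET probability plus marker cofactors, excluding cofactors
within a window (default 10 cM) of the test position; the LOD compares
the fits with and without the position term. Cofactors are chosen by
forward selection on AIC over single-marker logistic fits, at most 3. The
cofactor settings of the original analysis are not published; these
defaults are conventional for CIM. At a typed complete-data marker with
all cofactors excluded, the logistic fit is the saturated two-group
binomial model, so CIM reduces exactly to interval mapping there (a
property the tests pin).

## Survivor-only fine-mapping

Genotyping only survivors converts the penetrance contrast into an allele
frequency distortion: among survivors, P(HET at the causal locus) =
RR/(RR + 1) with RR = p_het/p_hom, and at map distance d the frequency
relaxes toward ½ through the two-state mixture with r(d). Each marker is
scored with the 1-df goodness-of-fit statistic
χ² = (n_res − n_sus)²/(n_res + n_sus) over non-missing genotypes.

The confidence interval is defined over typed markers, not a continuous
position: the contiguous run through the peak with χ²(peak) − χ²(m) ≤
drop, extended one flanking marker on each side, because at marker
resolution the causal gene may lie between the last included marker and
its neighbour. The drop is calibrated by simulation: for each simulated
survivor cohort (exactly n_survivors survivors retained; penetrances
parameterised as p_het = 2RR/(RR+1), p_hom = p_het/RR — any pair with the
stated ratio gives the same survivor genotype distribution, and this pair
keeps mean survival at ½ so rejection sampling is efficient), the minimal
covering drop is recorded, and the calibrated drop is the empirical
`coverage` quantile (default 0.95) of those minima. The default fixture —
12 evenly spaced markers on 3–27 cM with the causal locus at 10.3 cM —
stands in for the study's unpublished fine-mapping marker map, so the
calibrated drop is map-sensitive and should be recomputed for any real
marker panel. Simulations condition on exactly n_survivors; whether the
original analysis subsampled a larger cohort instead is unstated.

A binomial segregation-distortion test is exposed as a diagnostic but the
estimators are not adjusted for distortion.

## Allele-specific expression

The allele fraction is the pooled read count ratio ref/(ref + alt).
Technical replicates are pooled within their biological replicate
(technical noise is multinomial given the library; biological replicates
carry the extra-binomial variance), and with ≥3 biological replicates the
95% CI is a t-interval around the pooled estimate using the
between-replicate SD; otherwise the exact Clopper–Pearson interval on the
pooled counts. Fold-difference is the odds transform f/(1 − f).

The gDNA control is reported as a QC check (exact binomial test against
0.5, α = 0.01, plus a 0.05 equivalence margin) and is not used to
renormalise cDNA fractions, since the design predicts no bias and the
control verifies rather than corrects. Group comparisons between
haplotype classes use a quasibinomial logistic GLM — IRLS with dispersion
estimated from Pearson residuals, floored at the binomial value 1, and a
t reference on the residual degrees of freedom — so overdispersed
replicate counts do not overstate significance. Lines are tested
independently; no multiple-testing correction is applied.

## Loss-of-function annotation

Coordinates are HGVS-like: CDS positions 1-based from the A of ATG;
upstream positions c.−N relative to the start codon. Variants are applied
right-to-left so positions stay valid; overlapping variants and
ref-allele mismatches are errors. A premature stop is an in-frame stop
codon strictly before the reference terminal codon; the frameshift flag
follows the (length difference mod 3) rule applied to the actual edited
interval. Expression competence is the exact presence of the 21-bp
upstream motif AAATAAGGCTATCTGGGATCA (mismatch tolerance configurable,
default 0).

Each variant is scored alone; a genome with ≥2 distinct LoF variants is
"multiple" (the co-occurrence rule), with a joint evaluation as a fallback
for variants only disruptive in combination. Genomes genotyped for ≤50%
of the gene are "unscorable" and excluded from population frequencies.
The D/I haplotype path (DDD/DDI low-expression; DII/IDI/III expressing) is
reported alongside, never merged with, the sequence-based classification:
the expression-null state of the DDI haplotype is not identifiable from
sequence alone. Ancestral/derived polarity is configuration, not
inference.

## Selection statistics

F_ST uses the Weir–Cockerham (1984) ANOVA estimator specialised to
haploid samples (inbred fly genomes contribute one haplotype; a diploid
GT in input VCF counts as two haploid calls). The estimator can be
negative by sampling — at identical sample frequencies it equals
−1/(n_c − 1) — and is reported as computed; it is clamped to 0 only inside
the PBS log transform, where negative branch lengths would be
meaningless. Pairwise region comparisons offer per-site values and the
standard multi-locus ratio-of-sums Σa / Σ(a + within); which the original
figure used is unstated, so both are provided. PBS uses the natural log.

The empirical null filters sites by class (short introns are treated as
putatively neutral; the class is an input label, not inferred), pooled
minor-allele frequency ≥ 5% over all called haplotypes, and per-region
typing fraction > 40%. Outlier percentiles invert the type-7
(linear-interpolation) quantile; empirical p-values use the add-one rule
(1 + #{null ≥ x})/(1 + N) so p is never exactly zero.

## Synthetic-data generators

The generators reproduce the statistical structure the analyses assume
and nothing more. Population allele frequencies follow the
Balding–Nichols beta model (mean p, variance F·p(1−p)) with binomial
sampling — adequate for estimator calibration but without linkage,
coalescent history, admixture or selection dynamics; "selected" sites are
deterministic frequency shifts. Allelic counts are beta-binomial with
rho defaulting to 0.005 (mild technical overdispersion; no dispersion
value is published, and the tests estimate rather than assume the
resulting variance). No read-level sequences are simulated. Passing tests
therefore demonstrate correctness of the estimators under their assumed
sampling models, not robustness to alignment artefacts, reference bias,
linked selection or population structure in real data.

Every generator takes an explicit seed and draws from its own numpy
Generator; there is no global random state, and identical seeds give
bitwise-identical outputs.

## Problem sizes

The test suite and acceptance script use the cohort sizes of the study
design where they matter (152 survivors, 1,000 calibration simulations,
400-individual mapping cohorts, read depth 10,000) and smaller panels
(hundreds to a few thousand sites, tens of haplotypes per population) for
estimator calibration, chosen so the full suite runs in well under a
minute of simulation time while keeping Monte-Carlo error far below every
asserted tolerance.

## Known limitations

- The calibrated χ² drop depends on the marker map; the default evenly
  spaced 12-marker fixture is a stand-in for an unpublished panel.
- CIM uses a logistic (Haley–Knott-style) approximation at non-marker
  positions rather than a full mixture likelihood with cofactors.
- The short-intron site class is taken from input annotations; no intron
  length/position rules are applied internally.
- Single-gene scope for annotation; no genome-wide consequence prediction
  and no protein-domain modelling.
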