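# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that affect results.

## Meiosis model and biparental populations

All mapping assumes Haldane's model: no crossover interference, so the
recombination fraction between markers d cM apart is r = (1 − e^(−2d/100))/2
and intervals recombine independently. Gametes are simulated as Markov
mosaics of the two parental genomes with those switch probabilities.

DH lines each carry one gamete, so their observed recombinant fraction
estimates r directly. Selfed F∞ RIL genomes are also Markov under no
interference, with per-interval switch probability given by the
Haldane–Waddington limit R = 2r/(1+2r); two-point estimation inverts this
(r = R̂/(2(1−R̂)), capped at 0.5). The package does not model F2 or
backcross data, residual heterozygosity, or interference (a Kosambi option
was considered and deliberately left out: every downstream formula here is
derived under Haldane).

Segregation distortion is injected by biased allele resampling at selected
markers; genotyping error flips calls independently; missing data blanks
them. Defaults are missing = 0.05 and error = 0.005 — plausible
array/SSR-era rates chosen once, since observed studies report only their
filtering thresholds, not raw error rates.

## Single-map pipeline

Filtering drops markers with > 0.15 missing calls or a 1-df χ² test of the
1:1 segregation (on non-missing calls) with P < 1e−4; the χ² rule is the
operative distortion filter (the often-quoted 0.7:0.3 ratio cap coincides
with it only at particular sample sizes). Grouping is single-linkage
transitive closure over pairs with LOD ≥ 6; after cleanup the per-chromosome
data are re-merged at the relaxed thresholds rec ≤ 0.3, LOD ≥ 3.

Ordering maximizes the two-point composite likelihood of adjacent pairs,
which on a path equals minimizing the summed adjacent Haldane distances. The
search is greedy insertion seeded from the highest-LOD pair, followed by
2-opt segment reversal and an exhaustive sliding-window (size 4) ripple
until no move improves. On error-free data this criterion has the true order
as its optimum; the heuristic is validated against exhaustive permutation on
≤ 8 markers and recovers 20-marker orders at ρ ≥ 0.99 in ≥ 95% of seeds with
200 RILs. Orientation is canonicalized by putting the alphabetically smaller
end marker at position 0; ties in insertion break on marker name, so output
is deterministic and invariant to input order. Pairs with r ≥ 0.5 are
assigned a large finite distance (the Haldane distance at r = 0.49999) so
the objective stays finite.

Singleton correction blanks (never flips) a call that disagrees with both
immediate flanking calls when the flanks agree and each lies within the
window — 5 cM for RILs, 10 cM for DH populations, where singletons are
rarer but windows sparser. Detection runs on the original matrix, so the
pass is idempotent.

## Consensus mapping

Anchor pairs pool recombinant/non-recombinant counts across populations on
the meiotic scale: RIL observed counts are shrunk through the inverse
expansion before the 2×m contingency χ² heterogeneity test (df = m−1) and
before pooling, since meioses — not line genotypes — are the common
currency across population types. When heterogeneity is significant at
P < 0.001, populations are excluded one at a time by largest adjusted
standardized Pearson residual until the remainder is homogeneous or one
population remains; pooled r = Σk/Σn over the included populations and the
pooled LOD sums each population's LOD evaluated at the pooled rate
re-expanded to its observed scale. Framework grouping/ordering reuses the
single-map machinery on the pooled pair table; anchor subsets that never
reach the linkage thresholds split into separate groups, mirroring the
split-chromosome situation seen with sparse anchor coverage.

Unique markers are projected by linear interpolation between the two
nearest flanking anchors shared with the framework (consensus position
A1 + (m−a1)/(a2−a1)·(A2−A1)); beyond terminal anchors the scale of the two
nearest anchors extends linearly. Interpolation is exact at anchors and
order-preserving within each anchor interval; positional ties keep source
order, then name. Component groups sharing fewer than two anchors leave
their unique markers unplaced rather than guessing. Order conflicts between
component and consensus maps are reported through the collinearity
statistics (ρ, r², orientation-resolved), never auto-resolved.

## LD and the Sved model

The panel is haploid-coded: elite inbred accessions carry one allele per
locus, so r² and D′ come directly from haplotype frequencies on
pairwise-complete accessions. Multi-allelic loci are biallelified (each
allele vs the pool of the rest; columns with MAF < 0.10 dropped) and a
locus pair is summarized by the maximum over allele-pair combinations —
the most sensitive convention for detecting any allelic association; a
frequency-weighted D′ average is available behind a flag.

Decay of syntenic LD follows E[r² − 1/n] = 1/(α + βc) with c in Morgans and
β = k·Nₑ (k = 4 for autosomes); n in the sample-size adjustment is the
number of accessions, which makes the published fit internally consistent
(α = 1.69, Nₑ = 19.36, n = 183 give r²(0) ≈ 0.6 and the r² = 0.3 crossing
at 2.20 cM). α is fitted by default (start α = 1, β = 40, bounded least
squares); fixing α = 1 (the no-mutation form) is exposed as `fit_alpha=False`
since both conventions are in circulation. The decay distance inverts the
curve analytically and is defined only between the 1/n asymptote and the
prediction at zero. Background LD is the 95th percentile (linear
interpolation) of r² over non-syntenic pairs and syntenic pairs ≥ 50 cM
apart; LD blocks chain adjacent mapped markers with r² ≥ 0.3, a missing
adjacent estimate acting as a boundary.

## Differentiation

AMOVA is one-level and haploid with the pairwise-difference distance
(count of mismatching calls over shared loci): SSD within/among, variance
components by the standard expectations with the weighted average
subpopulation size n′, negative components floored at zero, and
F_ST = σ²a/(σ²a+σ²w). Permutation significance shuffles accessions across
subpopulations; the permutation comparison uses the *unfloored* statistic
so null P-values stay calibrated (flooring first would pile P at 1 whenever
the observed estimate hits the zero floor). The per-locus scan applies the
same estimator per subpopulation pair from allele counts, with vectorized
label permutations; monomorphic loci are undefined and non-significant.
Permutation was chosen over an F_ST-threshold lookup as the plainer reading
of "significance at P ≤ 0.01" for single-locus tests.

Differentiation patterns are classified from the set of significant pairs
with precedence 1 > 2 > 3: pattern 1 needs ≥ 7 of the 10 pairs, pattern 2
needs ≥ 3 of the 4 pairs involving the dryland lineage, pattern 3 needs
≥ 3 of the 4 pairs crossing {temperate, italian_early} × {mid, late}.

PIC = 1 − Σpᵢ² per locus; the standardized form divides by the
equifrequency maximum 1 − 1/k for the k observed alleles (monomorphic loci
score 0) — an explicit, testable normalization adopted because published
"standardized for allele number" indices rarely state their rule. The map
profile is a centered 3-marker sliding-window mean, truncated at group ends.

## Association mapping

Phenotypes enter as a long table (accession × environment, with macro-area
and latitude). Adjusted means center each environment at its own mean
before averaging within macro-area — a deliberate simplification of
augmented-design BLUP pipelines: any per-environment adjusted value can be
substituted, since the contract is only "one adjusted value per accession
per environment". Broad-sense heritability uses the line-mean form
h² = σ²G/(σ²G + σ²e/n) with components from a balanced one-way
random-effects ANOVA (incomplete accessions dropped).

The mixed model is plain (uncompressed) Q+K: compression is a scalability
device for panels far larger than this scale, and exact REML is preferable
and testable here. Variance components are estimated once on the null model
(intercept + Q with one column dropped for identifiability + covariates) by
maximizing the restricted likelihood in δ = σ²e/σ²g after a spectral
decomposition of K; each marker is then tested by a 1-df GLS F-test at
those components (the P3D approach). With K = I the transformed model is
exactly OLS, which anchors the calibration tests. Marker R² is the
incremental explained sum of squares on the GLS-transformed scale over the
transformed total — the published analyses do not define their R², so this
proportion-of-phenotypic-variance reading is documented as the package's
convention. Missing marker calls are mean-imputed for the scan; markers
collinear with the null design report F = 0, P = 1 with a diagnostic note,
which is also what makes two-pass major-locus conditioning behave sensibly
(the covariate's own association vanishes, linked markers attenuate).

The experiment-wise threshold divides α = 0.05 by the genome-wide LD-block
count; QTL regions collect markers at marker-wise P ≤ 0.01 in ≥ 1
macro-area, merging consecutive significant markers on a group when their
r² ≥ 0.3; the confidence interval pads the member span by 2.2 cM per side
(singletons: 4.4 cM total). Joint R² is the OLS fit of the overall adjusted
mean on all representative markers plus covariates, with collinear columns
harmlessly absorbed by the least-squares projection.

## The synthetic panel: what it does and does not emulate

The panel generator draws founders per subpopulation from shared global
allele frequencies (SSR loci: 2–4 alleles with Dirichlet frequencies; DArT
loci: biallelic), then runs discrete generations of random union of gametes
within subpopulations — each offspring is a single recombinant gamete, so
accessions stay fully inbred/haploid — with a per-parent admixture
probability of drawing from the whole metapopulation. Realized ancestry
fractions are tracked through the pedigree and returned as the Q matrix.

Defaults mirror the published panel's shape: five subpopulations of
11/55/26/56/35 accessions (183 total), Nₑ = 20 per subpopulation (the
published fitted Nₑ ≈ 19.4), admixture 0.1 — an island-model regime whose
equilibrium differentiation 1/(1 + 2·Nₑ·m) ≈ 0.2 sits near the published
overall F_ST of 0.172 — and 8 drift generations, enough to approach that
equilibrium while building distance-dependent LD. Phenotypes are additive:
small QTL effects plus two major loci whose effects scale with environment
latitude in opposite directions (emulating the opposed photoperiod-response
homoeologs), additive environment offsets and iid noise across 27
environments grouped into 5 macro-areas by latitude.

What it does not emulate — and therefore what passing tests do not show
about real data: mutation and marker homoplasy, ascertainment bias of array
markers, residual heterozygosity, pedigree-accurate breeding selection,
epistasis and genotype×environment interaction beyond the latitude scaling,
and genotyping-chemistry error structure. Short-range LD after only 8 drift
generations is weaker than the empirical panel's (fitted r²(0) well below
0.6), so Sved parameter-recovery tests use pairs generated directly from
the decay model (Beta-distributed around the curve), and the empirical-panel
checks are qualitative (monotone decay, background magnitude ~0.1).

## Numerical choices and problem sizes

Explicit seeds everywhere; a root seed spawns per-stage child seeds (kept
below 2³¹) via `numpy` SeedSequence, so pipelines are byte-reproducible.
Unlinked or unestimated pairs get the finite distance cap noted above;
0·log 0 := 0 in LOD computations; permutation P-values use the add-one
estimator (b+1)/(m+1). cM values are written with 2 decimals, full
precision in memory. Test and acceptance problem sizes (e.g. 20-marker ×
200-line order recovery over 50 seeds, 5,000 model-generated LD pairs,
~1,800 mixed-model null tests, pipeline demos with 90 true markers) were
chosen as the smallest designs whose Monte-Carlo error is comfortably inside
the asserted tolerances; the full suite runs in seconds.

## Known limitations

Ordering is two-point composite likelihood, not multipoint EM, so it does
not exploit partially missing genotypes as efficiently as Carthagene-style
multipoint mapping; heterogeneity exclusion is greedy (one population at a
time); the interpolation rule cannot place markers from component groups
sharing fewer than two anchors; AMOVA is single-level (no region/population
hierarchy); the mixed model tests one marker at a time with fixed variance
components rather than refitting REML per marker.
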