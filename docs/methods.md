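# Methods

## Study design emulated by the simulator

The synthetic study is a durum-wheat NAM: one recurrent parent crossed to
three donors, each cross selfed to F5-derived RILs (146/138/142, 426
progeny plus the four parents), genotyped at 1,678 SNPs on 14 chromosomes
spanning 1,723 cM (largest chromosome 179 cM, smallest 51 cM), and
phenotyped in eight environments — five with terminal moisture stress
during grain filling, three irrigated — in augmented designs of 10 blocks
of 48 plots, the four parents replicated once per block (spare plots
cycle through the checks).

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to the
map length in Morgans, positions uniform, no interference (Haldane).
Closed forms follow: recombinant fraction r(d) = (1 − e^(−2d))/2 and
residual heterozygosity 0.5^g after g selfings (0.0625 at F5), which the
tests verify by Monte Carlo. Mapping-function choice (Haldane vs Kosambi)
only matters for map estimation, which this package does not do; the
interference-free model keeps every simulator oracle analytic.

**Genetic values.** Planted QTL are purely additive; each attaches to the
nearest mapped marker (ties to the lower cM) so truth is recoverable from
the emitted genotype file alone. Defaults: three TKW loci on different
chromosomes with allele-substitution effects 1.5/1.2/1.0 g plus a 1.5 g
polygenic term, and two GY loci (60/50 kg/ha) plus a 110 kg/ha polygenic
term. Genotypes are coded as recurrent-allele dosage 0/1/2; the positive
allele is by convention the recurrent parent's.

**Phenotypes.** Plot value = environment main effect + line genetic value
+ Σ_k λ_k·g-score_k·env-loading_k (two interaction axes; λ per trait)
+ linear row/column trend + Gaussian residual. Environment means place
GY near 2,520 kg/ha (stressed) vs 4,251 kg/ha (irrigated) and TKW near
43 vs 45 g, the magnitude of a severe Mediterranean terminal drought.
Plot values are re-expressed as raw field measures (200-kernel sample
weight, plot grain weight over 1.5 m², spike counts per linear meter,
heading/maturity dates) so the trait-derivation stage is exercised.
Per-trait polygenic and residual SDs were set once so that entry-mean
heritabilities land near the strongly contrasting magnitudes typical of
these traits (TKW ≈ 0.9, GY ≈ 0.5); the planted QTL effects stay ≥ 0.5
within-environment phenotypic SD (as homozygous class differences) so
subfamily scans retain power.

**Climate.** Daily weather is drawn per growth-stage window (pre-sowing
month, vegetative, flowering, grain fill); stressed sites draw 5–20 mm of
grain-fill rain, irrigated sites 40–90 mm, so the moisture contrast is
expressed where the clustering stage looks for it.

What the generator does **not** emulate: dominance and epistasis,
selection during inbreeding, segregation distortion, genotype-dependent
phenology driving the climate windows, spatially autocorrelated (non-
linear) field trends, and array-intensity artifacts. Passing tests
therefore demonstrate correctness of the analysis chain under an additive,
well-behaved world, not robustness to those features of real data.

## Analysis choices

**Spatial adjustment.** The default model fits entry effects jointly with
a *linear* row + column trend per environment (backfitting to the OLS
solution; effects centred so the grand mean is preserved). A free
effect-per-row/column model is available (`model="levels"`) but is close
to saturated in an augmented design — ~480 plots against ~430 entry plus
~44 row/column parameters — which inflates the error of unreplicated
entry means roughly threefold and correspondingly deflates downstream
heritability; the 2-df linear trend removes the planted gradients exactly
while leaving entry means at plot-error precision. Both models remove a
purely additive linear trend exactly in the noiseless case.

**Combined analysis.** Method-of-moments on the environment × entry mean
table: MS_G = n_E·σ²g + MS_GE and MS_GE = σ²ge + σ²e/n̄. The two
interaction-side components are only separable when a plot-level error
variance is supplied; the pipeline estimates σ²e from the replicated
checks. Shrunk (BLUP-style) entry values use
h = σ²g/(σ²g + (σ²ge + σ²e/n̄)/n_E). Negative component estimates
truncate at zero. REML would be the field's default for unbalanced data;
the moment estimator is deterministic and oracle-checkable, and the
emulated design is balanced at the entry-mean level.

**Heritability** uses the entry-mean formula above. The bounds [0, 1],
monotonicity in σ²g and σ²e, and the TKW > GY ordering are tested.

**AMMI/AWAI.** Genotype scores use the symmetric scaling u_k·√λ_k; the
interaction share s_k = λ_k²/Σλ² is scale-free, so AWAI is homogeneous of
degree ½ in the interaction residual (the natural invariance under this
scaling). Axis significance is a Gollob-style F with df_k = g + e − 1 − 2k
against a supplied error mean square; without one, a sequential
pooled-residual test with a minimum interaction-share guard (0.5%) is
used, because the top noise axis always exceeds the pooled mean of the
rest and would otherwise be retained. At least one axis is kept whenever
the interaction sum of squares is non-negligible. Final rankings order by
performance (desc), AWAI (asc), then entry label for determinism.

**LD decay.** Pairwise r² is the squared dosage correlation (the panel is
near-homozygous, so haplotype-phase estimation adds nothing). The decay
distance is where a Hill–Weir expected-r² curve with finite-sample
correction, fitted by nonlinear least squares over intrachromosomal
pairs, crosses r² = 0.2; a nonparametric moving-average crossing is
reported alongside and used as fallback. If the curve never crosses the
threshold the distance is flagged undefined.

**Thresholds.** Effective tests M = round(map length / LD decay), minimum
1; genome-wide p threshold α/M and LOD threshold −log10(α/M). The r²
floor for reported associations squares the two-tailed Pearson critical
value at α = 0.05 for df = n − 2. A user threshold override exists
because published LOD cutoffs are not always reconstructible from their
stated inputs.

**Scans.** The GLM scan tests each marker's dosage by partial F against
intercept + subpopulation dummies (Q) + days-to-heading, vectorised by
Frisch–Waugh residualisation; missing dosages are mean-imputed per
marker, and monomorphic or covariate-collinear markers are skipped with a
reason. The interval scan is classical composite interval mapping within
one biparental subfamily: forward–backward stepwise cofactor selection at
p = 0.001 (capped at n/10 cofactors), then Haley–Knott regression on a
4 cM grid using flanking-marker posterior dosages (Haldane, one-sided at
chromosome ends), with same-chromosome cofactors excluded within 10 cM of
the test position; LOD = (n/2)·log10(RSS₀/RSS₁). Cofactor-window edges
create genuine (documented) steps in the profile; the grid itself does
not.

**QTL calling.** MTAs above both thresholds merge by single-linkage
chaining within a chromosome when gaps are < 2 × LD decay; the peak is
the member with maximal LOD; a QTL is *stable* when its member MTAs span
≥ 2 single environments and both methods. Combined-cluster and AWAI scan
contexts annotate QTLs but do not count toward the environment tally.

**Pyramiding.** Haplotype classes are the joint +/− patterns at the
chosen peak markers over lines with complete, homozygous calls (lines
with missing or heterozygous calls are excluded and counted; F5 panels
retain ~6% residual heterozygosity, so the warning tolerance is 10%).
One-way ANOVA with LSD letters compares class means; the percent
advantage is 100·(best − worst)/best, the definition consistent with a
25.6% gap between 43 g and 32 g class means.

**Validation metrics.** Sensitivity/specificity are the shares of correct
+/− calls among the top/bottom n (default 20) lines by trait;
"accuracy" is ambiguous in common usage, so both a median-split
denominator over all scored lines (default) and an extremes-only variant
are implemented. Rank ties at the n-th boundary break by line label.

## Problem sizes and numerics

The default study (426 RILs × 1,678 SNPs, 8 environments) runs the whole
pipeline in seconds; tests use 10,000 gametes for recombination checks,
1,000 permutations of a 400 × 500 panel for scan calibration, and 20
seeded pipeline replicates for recovery — sizes at which every
Monte-Carlo band in the suite is a 3-SE interval around a closed form.
Backfitting iterates to |Δ| < 1e-12 (cap 5,000 sweeps); SVD reconstruction
is asserted to 1e-10 and oracle agreement to 1e-8; consensus-map
rescaling clamps ~1e-15 negative round-off at zero. All randomness flows
from explicit `numpy.random.Generator` seeds; equal seeds give
bit-identical outputs.

## Known limitations

Single-stage mixed-model alternatives (kinship-random-effect GWAS,
REML/spline spatial models) are out of scope by design. The interval scan
treats F5 RILs as gamete mosaics for posterior dosage (het calls enter as
0.5), a standard approximation that slightly compresses effective map
distances. The effective-test correction assumes a single genome-wide
decay distance. The heritability formula is one common entry-mean
variant; cited "modified" estimators differ in how replication enters and
are not reproduced here.
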