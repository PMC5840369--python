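# Methods

`domescan` implements a haplotype-differentiation pipeline for detecting
selection signatures that separate domestic populations from their wild
ancestors in two genera, for testing whether those signatures converge
across the genera, and for characterizing candidate regions by their
diversity pattern (Δπ) and their deleterious-mutation (genetic-load)
content. This note records the models, the estimators, the tunable
parameters, and the design choices, including what the synthetic-data
generator does and does not emulate.

## Study design assumed by the pipeline

Per genus the pipeline expects four groups: one wild population, two
traditionally managed domestic populations (the statistical test groups),
and a multi-breed world panel. The scan contrasts the wild group against
each domestic group separately and keeps signals found in both contrasts;
the world panel is carried through haplotype-consistency inspection only
and never enters a statistical test, because a multi-breed panel violates
the single-population drift model.

## Drift null: Reynolds distances, NJ tree, kinship matrix

Neutral differentiation is modeled as allele-frequency drift with
population covariance **F**: under the Balding–Nichols construction a
population at drift distance `c` from the ancestor has allele frequency
with mean `p0` and variance `c·p0(1−p0)`.

`build_kinship` estimates **F** from the data:

1. Reynolds genetic distances `D` between all group pairs, on a seeded
   random subsample of sites (default fraction 1%, floored at 2,000 sites —
   on whole-genome data 1% is hundreds of thousands of variants, but on a
   desk-scale panel it would be a handful, so the floor keeps the estimate
   usable). The ratio-of-sums (multi-locus) dialect is the default; a
   per-locus-averaged variant is available.
2. A neighbor-joining tree is fitted to **2D**. The factor of two matters:
   by simulation under Balding–Nichols, the Reynolds distance between two
   populations estimates the *mean* of their two drift accumulations, while
   the covariance needs path *sums*; without the factor every FLK score is
   exactly doubled relative to its χ² reference.
3. The tree is midpoint-rooted (no outgroup is designated; rooting is
   configurable) and negative NJ branch lengths are clamped to zero.
4. `F[i,j]` is the branch length shared by the root-to-`i` and root-to-`j`
   paths; `F[i,i]` the root-to-`i` path length. This matrix is positive
   semi-definite by construction.

Caveat: the plain Reynolds estimator computed from sample frequencies
carries a ~`1/(2n)` inflation per population (finite-sample noise looks
like drift). The pipeline does not correct for it; the empirical χ²
calibration of scores (below) absorbs the resulting scale error, and only
the FLK/χ²-asymptotic route assumes an unbiased **F**.

## FLK and hapFLK

FLK for one SNP with population frequency vector `p`:

    p̂0 = (1ᵀF⁻¹p)/(1ᵀF⁻¹1)            (GLS weighted mean)
    FLK = (p − p̂0·1)ᵀ [p̂0(1−p̂0) F]⁻¹ (p − p̂0·1)

Under neutrality FLK is asymptotically χ² with `n_pops − 1` degrees of
freedom. Scores are zeroed when `p̂0` is within 1e-6 of fixation (the
variance model degenerates there and would otherwise explode).

hapFLK replaces allele frequencies with local haplotype-cluster
frequencies. The LD model is the Scheet–Stephens haplotype-cluster HMM
(fastPHASE model): `K` clusters (default 25); per-site, per-cluster ALT
emission probabilities `α`; per-site cluster weights `w`; per-interval
switch probabilities `ρ`. Between adjacent sites a haplotype keeps its
cluster or, with probability `ρ`, redraws from `w`. For unphased genotypes
the hidden state is an ordered cluster pair whose components transition
independently, so phase uncertainty is integrated exactly (no
pseudo-phasing); ordered pairs give the same likelihood as the unordered
formulation up to a data-independent constant and identical posteriors.
Fitting is exact EM (jump-parameterized Baum–Welch): the log-likelihood is
monotone non-decreasing, checked in tests to 1e-8 relative tolerance.
Probabilities are floored at 1e-12, which bounds any monotonicity
violation far below that tolerance. Several independent seeded EM runs are
kept (default 5); hapFLK is the mean over runs of the per-run score

    hapFLK(s) = Σ_k FLK-quadratic-form(cluster-k frequencies at s)

with the ancestral cluster frequency estimated per cluster exactly as
`p̂0`. Clusters whose `p̂0` is at fixation contribute zero. The pair-state
forward–backward recursions are the pipeline's hot loop and run through
numba-compiled kernels; a pure-numpy reference implementation of the same
E-step is kept in the module and the two are asserted equal (1e-10) in the
test suite.

EM details: `α` initialized from site frequencies plus seeded noise, `w`
near-uniform, `ρ` from `1 − exp(−10⁻⁵·distance)`; convergence when the
relative log-likelihood change drops below `em_tol` (default 1e-6) or at
`em_max_iter` (default 100).

## Score calibration, combination, and region calling

hapFLK has no analytic null, so scores are fitted genome-wide to a scaled
χ²: `score ~ a·χ²_d`. The top `trim_upper` fraction of scores (default 1%)
is removed first so that true sweeps do not inflate the fitted null.
Because trimming truncates the sample, naive moment matching is biased
(for χ²₄ and 1% trimming it returns d ≈ 4.7); the estimator instead
matches the observed trimmed mean and variance to the moments of the
*truncated* scaled χ², solving for `d` on the scale-free variance/mean²
ratio by bracketed root finding, then recovering `a`. On simulated
`a·χ²_d` scores this recovers `d` within ±0.2 and `a` within ±5% at
m=10⁵. The trim fraction must exceed the fraction of truly swept SNPs: at
desk scale, where planted sweeps can occupy several percent of all SNPs,
the analyses in the test suite and acceptance script use `trim_upper=0.10`;
the genome-scale default stays 0.01.

Per contrast, FLK scores are calibrated by the same procedure (their
combined p-value distribution is used only for the within-region top-SNP
threshold `p < 10⁻⁴`, not for FDR). The two wild-vs-domestic contrast
p-values are combined per SNP by Stouffer's method
(`z_i = Φ⁻¹(1−p_i)`, `p = 1 − Φ((z₁+z₂)/√2)`), converted to q-values
(Storey–Tibshirani with `π̂₀` at λ=0.5; Benjamini–Hochberg available as the
`π₀=1` special case; when every p ≤ λ makes `π̂₀` zero the plug-in falls
back to `1/m`). SNPs with `q < 10⁻²` (strict) are merged into candidate
regions when consecutive retained SNPs are less than 50 kb apart (strict);
single-SNP regions are flagged.

### Haplotype-consistency filter

The underlying visual check asks whether the three domestic groups carry
the *same* swept haplotype. Quantification: haplotypes over the region's
SNPs are clustered by neighbor joining on 1 − allele-identity distances,
the tree is midpoint-rooted, and the region passes if **some clade**
contains at least 50% of every domestic group's haplotypes (world panel
included when present) and fewer than 50% of wild haplotypes. All clades
are inspected, not only the root bipartition: when many swept haplotypes
are nearly identical the midpoint root frequently falls inside the sweep
clade, and a root-only rule would split the clade across the root and
reject genuine shared sweeps. Regions with fewer than two SNPs are
`indeterminate`. The 50% threshold is configurable; results that depend on
it should be labeled as such. Failing regions are dropped by default
(`drop_inconsistent`).

### Annotation

A gene is assigned to a region when the region ± 50 kb overlaps the gene
± 5 kb (both 1-based inclusive); the closest gene to the top signal (the
lowest-q SNP, ties broken by position) is recorded. SNP-class composition
(intergenic / up-downstream / intronic / exonic labels are consumed, not
predicted) of top-FLK SNPs versus all scanned SNPs is compared by Pearson
χ² against background proportions, merging zero-expectation cells.

## Cross-genus convergence

SNPs of genus B are stratified a priori into **shared** (inside the
homology-map image of any genus-A candidate region) and **general** (the
rest). Homology is consumed as aligned segment pairs with an affine
per-segment transform (strand − reverses within-segment orientation);
positions in alignment gaps are unmapped, and a region spanning a gap
contributes only its mapped portion. q-values are recomputed independently
within each stratum (stratified FDR), and stratified `q < 10⁻²` is the
final significance criterion, with the same 50-kb merging.

The convergence curve asks whether stronger selection evidence in genus A
predicts selection in genus B: for each threshold `t` on a 10-point
log-spaced grid from 0.2 down to 0.002, genus-A regions with minimum
member q ≤ `t` (region-level stringency = min member q; the region pool is
called at the loosest grid point so that membership actually varies along
the grid) are mapped to B, and `π₁ = 1 − π̂₀` of the genus-B p-values in
the resulting stratum is recorded (`π̂₀ = #{p>λ}/(m(1−λ))`, λ=0.5, clamped
to [0,1]). The curve's summary is the Spearman correlation of `−log t`
with `π₁` over defined grid points; undefined points (no qualifying
region, empty stratum) are excluded, and an all-flat curve leaves the
correlation undefined (reported as NaN, interpreted as "no trend").

## Δπ classification

For each candidate region,

    Δπ = (π_wild − π_dom)_region − (π_wild − π_dom)_genome-wide

with `π_dom` the average of the two traditional domestic groups' π and π
the mean per-site pairwise-difference proportion (differing haplotype
pairs over all pairs). Positive Δπ (relative diversity deficit in
domestics) is classified directional/stabilizing selection in domestics;
negative Δπ indicates relaxed or diversifying selection in domestics or a
sweep in the wilds. The genome-wide term uses all filtered panel sites (a
flag could restrict it; scan-filtered sites are what the pipeline has).

## Genetic load

Sites with conservation score ≥ 1.5 (phyloP-like, consumed from a track)
are "constrained". Per individual, the total load is the sum of scores at
constrained sites carried homozygous for the derived (ALT) allele, divided
by the number of analyzed positions (constrained sites present in the
panel — the denominator choice is documented here because "all analyzed
positions" is ambiguous between all coding and all constrained sites).
Heterozygotes are excluded so no dominance coefficient is needed. The load
*per homozygous position* divides the same score sum by the individual's
count of homozygous genotypes at constrained sites and is the quantity
correlated with the inbreeding coefficient F (method-of-moments
`(O_hom − E_hom)/(L − E_hom)` with the `n/(n−1)` small-sample correction,
computed within each group's own gene pool). Gene-level load (score sum
over constrained sites inside the gene body) is compared between domestic
and wild individuals by a one-sided Mann–Whitney/Wilcoxon rank-sum test
(alternative: domestics carry more load), Benjamini–Hochberg adjusted,
significant at adjusted p < 0.05.

## Synthetic data generator

The generator produces paired two-genus panels with known truth so every
stage is testable without external data.

* **Population structure.** Ancestral allele frequencies are uniform on
  (0.05, 0.95); each branch of a rooted population tree perturbs
  frequencies by a Beta (Balding–Nichols) draw with variance `c·p(1−p)`.
  The default tree splits wild from a domestic ancestor (drifts
  0.03–0.06); group sizes default to 15 wild / 20 + 20 domestic / 14 world
  panel, matching a realistic resequencing design.
* **Linkage disequilibrium.** Each population receives a founder pool
  (default 30 haplotypes drawn from its frequencies); individual
  haplotypes are mosaics of the pool with per-bp switch probability 10⁻⁵.
  This produces block-wise LD without a coalescent dependency. Note the
  finite pool adds real extra drift of order 1/pool-size on top of the
  tree — calibration checks that target the Balding–Nichols expectation
  exactly (e.g. FST ≈ branch drift) therefore use a large pool (300) and a
  fast switch rate.
* **Sweeps.** A sweep replaces each target-group haplotype, with
  probability `intensity`, by one founder haplotype inside the interval.
  Domestic sweeps target both domestic groups and (by default) the world
  panel; *relaxation* is modeled as the mirror event, a sweep in the wild
  group only, producing locally higher domestic diversity (negative Δπ).
  Sweeps marked shared across genera are placed at homologous coordinates.
  Intensities are free parameters, not estimates of real sweeps; scenario
  builders can grade them to emulate the continuum of selection strengths
  in real data (the convergence curve is only informative when region
  stringency varies).
* **Homology.** Aligned segment pairs with optional offsets, strand flips
  and gaps; the default plan covers ≥ 90% of genus-1 coordinates, maps the
  sweep-bearing chromosome by identity and puts a gap + offset on the
  neutral chromosome.
* **Conservation and load.** Genes tile alternate blocks of consecutive
  SNPs; a fraction of genic sites is constrained with scores
  1.5 + Exponential(1); other sites score below 1.5. Load-shifted genes
  receive excess homozygous-ALT genotypes in the shift-target groups.
  Optional per-individual autozygosity (`inbreeding_range`) makes a random
  fraction of each individual's sites homozygous, creating genuine F
  variation; `hom_coupling` then plants homozygous-derived genotypes at
  constrained sites with probability proportional to each individual's
  excess homozygosity (min–max scaled), guaranteeing a monotone F-load
  relationship by construction.
* **Determinism.** All randomness flows from the scenario seed through
  `numpy.random.SeedSequence`; identical scenario + seed gives
  byte-identical VCF output.

What the generator does **not** emulate: realistic recombination maps,
mutation-rate heterogeneity, demographic trajectories through time,
admixture, genotyping error or missingness, and any coupling between
sweeps and gene annotations. Passing tests therefore demonstrate that the
statistical machinery behaves as designed under its own model assumptions,
not that the pipeline's power or FDR would be identical on real
resequencing data.

## Problem sizes used in the test suite and acceptance script

The full study is genome-scale; the packaged analyses run at desk scale,
chosen once as follows:

* Sweep recovery: two genera, 2 chromosomes × 3,000 SNPs each, six
  domestic sweeps per genus at intensity 0.9 (three shared), K=8, three EM
  runs, `trim_upper=0.10`. K is reduced from the genome-scale default of
  25 because a founder pool of 30 supports far less local haplotype
  diversity than whole-genome data.
* Convergence: 20 replicates per condition at 2 × 1,000 SNPs, K=6, two EM
  runs; four shared sweeps at 0.9 plus four genus-specific sweeps graded
  0.4–0.7 (null condition: eight genus-specific, no shared).
* Δπ classification: 20 replicates, 2 × 700 SNPs, intensity 0.85, truth
  intervals as regions.
* Genetic load: ~500 genes, 10% shifted, on a low-drift panel (star tree,
  0.002 per branch, pool 300) — between-group drift otherwise creates
  real per-gene load differences that are indistinguishable from planted
  shifts; the low-drift design isolates the load machinery. The F-load
  correlation uses `inbreeding_range=(0, 0.3)` and `hom_coupling=0.8`.
* Null calibrations: 10⁴ Balding–Nichols SNPs (FLK), 10⁵ scores (χ² fit).

## Known limitations

* The χ²-calibration estimator is a transparent stand-in for the original
  external fitting script; agreement is by calibration properties, not
  equality.
* The consistency heuristic quantifies a visual check; its 50% thresholds
  are a choice, and borderline regions are sensitive to them.
* The plain Reynolds estimator's finite-sample inflation biases the
  kinship scale upward on small panels (absorbed by the empirical score
  calibration, but visible in the covariance matrix itself).
* Homology is consumed from one map per direction; conflicts between the
  two directions of a reciprocal alignment are not arbitrated.
* π̂₀ on very small strata (tens of SNPs) is noisy; convergence-curve
  points built on such strata inherit that noise.
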