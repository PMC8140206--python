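# Methods

## Model and assumptions

The core estimator is a Poisson Random Field (PRF) fit to two unfolded
site frequency spectra that share a sample size n: a neutral reference
(4-fold degenerate sites) and a focal class. Sites are assumed
independent (free recombination between SNPs), sampled from a single
pooled population of fully genotyped diploids (one fixed n per SFS, as
sites with any missing genotype are filtered out), and at mutation–
selection–drift equilibrium. Selected mutations are unconditionally
deleterious with population-scaled effect magnitude γ = 4Nₑs drawn from a
Gamma(a, b) distribution ("reflected" gamma; no beneficial mass). The
expected count in frequency class i is

    neutral:   e_i = θ_n r_i / i
    selected:  e_i = θ_s r_i ∫₀^∞ f_Γ(γ; a, b) H(i; n, −γ) dγ

with polarization-error mixing e_i′ = (1−ε)e_i + ε e₍ₙ₋ᵢ₎ applied per
spectrum, and

    H(i; n, S) = ∫₀¹ C(n,i) x^i (1−x)^{n−i}
                 (1 − e^{−S(1−x)}) / ((1 − e^{−S}) x(1−x)) dx,

the binomially sampled stationary density of a semidominant allele with
scaled coefficient S. H(i; n, 0) = 1/i, so the selected expectation
collapses onto the neutral one as a·b → 0.

The distortion vector r is shared between the two spectra; this is the
demography correction in the style of Eyre-Walker, Woolfit & Phelps
(2006): any force that perturbs frequency classes identically in both
classes (population size change, pooled structure) is absorbed by r and
does not contaminate the selection parameters. r₁ is fixed to 1 — without
an anchor θ·r is unidentifiable. Each spectrum keeps its own θ and ε.
The r-vector parameterization is this package's definition of the
correction, not a claim of bit-compatibility with any external tool.

Observed counts are independent Poisson, giving log-likelihood
Σ (x_i log e_i′ − e_i′) over both spectra with constants dropped.

## Downstream quantities

* Binned DFE: (F(1), F(10)−F(1), F(100)−F(10), 1−F(100)) of the fitted
  Gamma CDF — effectively neutral, weakly deleterious, deleterious,
  strongly deleterious.
* μ⁻ = E_Γ[γ/(e^γ−1)]: the DFE-averaged Kimura fixation probability of a
  deleterious semidominant mutation relative to neutral, with the
  integrand taken as 1 at γ → 0, so μ⁻ → 1 in the neutral limit and → 0
  under strong selection.
* α = (d_N − d_S μ⁻)/d_N, where d_N and d_S are K80 divergences on the
  focal branch extracted from the three pairwise distances among salmon,
  brown trout, and Arctic charr by the unrooted three-point formula
  (d_st + d_sc − d_tc)/2, floored at zero (the floor is this package's
  choice for non-additive noise; strong non-additivity is logged).
  Negative α is reported as such — it indicates no evidence of positive
  selection, not an error.
* π = Σ i(n−i)x_i / (C(n,2) L) and Tajima's D with the standard 1989
  constants, computed from the SFS (equivalent to genotype-matrix
  definitions under the complete-genotype filter). D is undefined (NaN)
  with no segregating sites and propagates as missing.

## Tunable parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| n_chromosomes | 62 | chromosomes | 2 × 31 fully genotyped diploids, the emulated study design |
| depth bounds | [4, 16] | mean per-site depth (×) | half / twice the 8× mean coverage; boundary values retained ("below"/"above" are exclusive) |
| promoter window | [−1000, +100] | bp around TSS, strand-aware, closed | conventional promoter definition for peak classification |
| DFE bin edges | 1, 10, 100 | γ = 4Nₑs | conventional effect-size bins |
| bootstrap B | 100 | resampling rounds | smallest attainable two-sided p is 2/B = 0.02, stated in outputs |
| ε | [0, 0.5] | probability | 0.5 means polarization carries no information |
| fit starts | 10 | — | one moment-based start plus seeded dispersed starts; the spread of optimum log-likelihoods across starts is reported as a flat-direction diagnostic |

## Numerical choices

* H(i; n, S) is evaluated by adaptive quadrature (absolute tolerance
  1e−12) with a log-space form of the selection ratio, stable to
  |S| ≈ 1e8; for S < −50 the quadrature is split at the concentration
  scale 1/|S|. |S| < 1e−8 returns the analytic 1/i.
* For fitting, H(i; n, −γ) is tabulated once per n on a log grid
  (γ ∈ [1e−6, 1e6], 16 points/decade) and interpolated by cubic spline;
  the outer integral over the gamma density uses composite Gauss–Legendre
  in log γ (10 nodes/decade) with analytic corrections for mass beyond
  the grid (H = 1/i below; the strong-selection asymptote
  C(n,i)(i−1)!/γ^i above). The fast path is validated in the test suite
  against direct nested adaptive quadrature to 1e−6 relative error at the
  canonical parameter sets; residual error is confined to classes whose
  expected counts are negligible.
* Optimization: L-BFGS-B on log-transformed positive parameters and
  (scaled) logit-transformed ε, bounds wide enough to be inactive at
  interior optima. All starts failing produces an explicit error, never a
  silent best-effort.
* μ⁻ uses adaptive quadrature on the scale-standardized variable
  (t = γ/b) split at max(a, 1), so small shapes and extreme scales do not
  defeat the subdivision; tolerance 1e−9 relative.
* K80 saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an explicit error.
* Coordinates are 0-based half-open internally; GFF3/VCF conversion
  happens only at I/O boundaries. Depth bounds are inclusive. Equidistant
  peak-to-TSS ties break to the lexicographically smaller gene id; peak
  position is the interval midpoint (integer floor).
* Category precedence for overlapping features is CDS > UTR > intron >
  intergenic; peak and repeat overlap are orthogonal flags; 2- and 3-fold
  degenerate sites are labelled but belong to neither the 0-fold nor the
  4-fold set.

## Synthetic data: what it emulates and what it does not

`simulate_sfs` draws independent Poisson counts around the model's own
expected spectrum — the exact generating process the estimator assumes —
so parameter-recovery tests are well-posed. It does not emulate linkage,
coalescent noise (which makes classes positively correlated), population
structure beyond the r-vector, or beneficial mutations. Passing recovery
tests therefore demonstrates correctness of the likelihood and optimizer,
not robustness to model misspecification on real data.

`simulate_triplet_alignment` evolves the three species independently from
a common ancestor on a star topology under K80 with no among-site rate
variation — the minimal model sufficient to test parsimony polarization
and distance estimation. `generate_toy_genome` builds genes with
UTR/CDS/intron structure (CDS free of internal stops), peaks, repeats,
homeoblock pairs with reploidization ages, and ohnolog pairs with
expression values; it is internally consistent bookkeeping, not a model
of real genome architecture. The construction-time category and
degeneracy truth arrays are retained so annotation is tested against the
generator's own ledger.

Mis-polarization in the triplet tests is defined for planted
polymorphisms: the salmon tip base is the true ancestral allele of a
fresh derived variant, so the error rate rises with the salmon branch
length as the outgroups drift away from the salmon lineage.

## Bootstrap

Resampling is by gene (with replacement, same block count), the natural
exchangeable unit when sites within a gene are linked; intergenic sites
attach to the nearest TSS's gene. The difference test reports the doubled
one-sided sign frequency of the bootstrap difference distribution capped
at 1 — a standard percentile-bootstrap interpretation chosen here because
no specific test is canonical. Callable sites are scaled by the resampled
share of blocks, which matches per-gene bookkeeping when gene sizes are
comparable. Replicates in which the statistic fails are recorded and
excluded; more than 20% failures fails the whole bootstrap.

## Problem sizes

Tests and the acceptance script run at deliberately modest scale chosen
to exercise every code path while staying convenient on a laptop: n = 20
chromosomes and θ = 10⁴ for DFE recovery (100 replicates in the test
suite, 30 in the acceptance script, 3 optimization starts each), 30 kb–
200 kb triplet alignments, a 2-chromosome × 300 kb toy genome with 40
genes and 80 peaks, and B = 100 bootstrap rounds. The full study design
(n = 62) is the simulator default.

## Known limitations

* The DFE likelihood treats frequency classes as independent Poisson;
  with real linked data the implied confidence statements are too tight,
  which is why uncertainty is reported via the gene bootstrap instead.
* ε and r are partially confounded with the selection parameters in small
  samples; individual shape/scale estimates are sloppy (they trade off
  along a ridge) and only binned proportions are reported as primary
  output.
* The three-point branch extraction assumes additive distances; rate
  variation among lineages biases it.
* Parsimony polarization is biased at high divergence; the ε parameter
  absorbs residual mis-polarization but was not designed for gross
  misidentification rates.
* No beneficial-mutation class, indel model, or codon model is
  implemented.
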