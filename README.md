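# wgdreg

Population-genomic inference of selection on regulatory elements in a
genome shaped by an ancient whole-genome duplication (WGD), modelled on the
Atlantic salmon (*Salmo salar*) system: H3K27ac peaks mark putative
enhancers and promoters, ohnologs are WGD-derived gene duplicates, and
homeoblocks are the large duplicated genome regions they reside in.

The package is for population geneticists who want to go from a filtered
SNP call set plus genome annotation to per-category diversity statistics,
a maximum-likelihood distribution of fitness effects (DFE), and the
proportion of adaptive substitutions (α) — with gene-level bootstrap
uncertainty — and to quantify regulatory divergence between duplicated
genes and genome blocks. A synthetic-data module generates every input the
pipeline consumes, so all stages are testable without any downloads.

## The model

Sites are classified (CDS > UTR > intron > intergenic, with 0-fold/4-fold
codon degeneracy inside CDS and H3K27ac peak overlap as a flag), SNPs are
polarized by strict three-taxon parsimony (brown trout and Arctic charr
must agree and match a salmon allele), and each category yields an
unfolded site frequency spectrum (SFS) x₁..x₍ₙ₋₁₎ with callable-site
count L.

The DFE is fit jointly to a neutral reference SFS (4-fold degenerate
sites) and a focal SFS under a Poisson Random Field model. Expected counts
at derived-allele frequency i out of n chromosomes are

    neutral:   e_i = θ_n · r_i / i
    selected:  e_i = θ_s · r_i · ∫ f_Γ(γ; a, b) H(i; n, −γ) dγ

followed by polarization-error mixing e_i′ = (1−ε)e_i + ε·e₍ₙ₋ᵢ₎, where
θ = 4Nₑμ per class, γ = 4Nₑs is the gamma-distributed magnitude of
deleterious effects (shape a, scale b; "reflected" gamma — no beneficial
mass), r is a distortion vector shared between the two spectra that
absorbs demography (r₁ ≡ 1), and H is the standard PRF sampling integral.
Counts are independent Poisson; the likelihood is maximized by bounded
quasi-Newton from multiple seeded starts. Results are summarized as the
proportions of mutations in four bins of γ: ≤1 (effectively neutral),
(1,10], (10,100], and >100.

From the fitted DFE, the mean relative fixation probability of deleterious
mutations is μ⁻ = ∫ f_Γ(γ; a, b) γ/(e^γ − 1) dγ, and with K80 divergence
d_N (focal category) and d_S (4-fold) on the salmon branch — extracted
from the three pairwise distances by the three-point formula — the
proportion of substitutions fixed by positive selection is

    α = (d_N − d_S·μ⁻) / d_N.

Uncertainty for π, Tajima's D, DFE bins, and α comes from resampling genes
with replacement (default B = 100) and recomputing each statistic from
scratch, including DFE refits.

## Worked example

Simulate paired spectra under a known DFE and refit it:

```python
import numpy as np
from wgdreg import SimConfig, simulate_sfs, fit_dfe, bin_dfe

cfg = SimConfig(n_chromosomes=20, theta_neutral=1e4, theta_selected=1e4,
                shape_a=0.5, scale_b=400.0)
rng = np.random.default_rng(42)
neutral = simulate_sfs(cfg, selected=False, rng=rng)
selected = simulate_sfs(cfg, selected=True, rng=rng)
fit = fit_dfe(neutral, selected, n_starts=3, seed=1)
print("generating bins:", np.round(bin_dfe(0.5, 400.0), 3))
print("estimated bins: ", np.round(fit.bins, 3))
print("shape %.2f scale %.0f" % (fit.model.shape, fit.model.scale))
```

prints

```
generating bins: [0.056 0.121 0.344 0.48 ]
estimated bins:  [0.062 0.137 0.384 0.417]
shape 0.51 scale 294
```

i.e. a single simulated data set recovers the generating bin proportions
to within a few percentage points (the shape parameter is estimated well;
shape and scale trade off individually, which is why results are reported
as bins). The same objects drive the full pipeline: `wgdreg simulate --out
toy/` writes a complete toy data set, and `wgdreg run --config config.yaml`
executes annotation → polarization → SFS → summary statistics → DFE →
divergence/α → bootstrap (→ peak/ohnolog/homeoblock divergence), writing
per-stage TSV/JSON and a manifest that makes reruns bit-identical.

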