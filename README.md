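# codonsel

Codon usage bias and the strength of selection on synonymous sites, from
population samples of protein-coding haplotypes.

In most genomes synonymous codons are used unequally. The standard
population-genetic explanation balances genetic drift, mutational bias
(typically toward A/T) and weak selection favouring a set of "major"
(often G/C-ending) codons — so synonymous sites, despite not changing the
protein, carry a detectable signature of selection in their site frequency
spectrum (SFS). `codonsel` implements the full analysis chain for testing
this on a chromosome-scale sample of haplotypes with an outgroup, as in
*Drosophila* third-chromosome inversion systems:

- **Codon statistics** — major/minor codon identification from pooled
  usage with per-amino-acid G-tests; ENC, Fop and CAI per gene; an
  amino-acid-composition randomization filter; nucleotide composition and
  GC3.
- **Polymorphism** — Nei–Gojobori synonymous/nonsynonymous site counts,
  π_S, Watterson's θ, Tajima's D; outgroup polarization of mutations into
  preferred (minor→major) and unpreferred (major→minor) classes and
  GC→AT / AT→GC directions; SFS construction over major/minor codon
  states.
- **Akashi's translational-accuracy test** — per-amino-acid 2×2 tables of
  major/minor codons at conserved/variable positions, odds ratio
  ψ = ad/bc, Mantel–Haenszel pooling.
- **SFS selection inference** — the mutation–selection–drift model with
  scaled mutation rates θ01, θ10 (bias κ = θ10/θ01) and selection
  γ = 4N_e·s on the focal allele. At equilibrium
  p_i ∝ C(n,i)·B(i+θ01, n−i+θ10)·₁F₁(i+θ01; n+θ01+θ10; γ); the full model
  (L1) adds a one-step population expansion (g, τ) solved by a
  Crank–Nicolson scheme on the backward diffusion. Maximum-likelihood
  fitting (multi-start Nelder–Mead), likelihood-ratio tests between
  L1/L0/NS, and γ estimated within quantile bins of codon bias or
  recombination rate.
- **Synthetic data** — a generator producing haplotype alignments, gene
  models and recombination annotations with the statistical structure the
  analysis assumes, so every stage is testable without external data.

## Worked example

Fit the selection model to an SFS simulated under known parameters:

```python
import numpy as np
from codonsel import SelectionParams, fit_model, lrt
from codonsel.synthetic_data import simulate_sfs

truth = SelectionParams(theta01=0.005, theta10=0.005 * 2.23,
                        gamma=0.788, g=3.70, tau=0.026)
counts = simulate_sfs(truth, n=47, n_sites=1_000_000, seed=1)

l1 = fit_model(counts, model="L1", n_starts=6, seed=1)
ns = fit_model(counts, model="NS", n_starts=6, seed=1)
chi2, p = lrt(l1, ns, df=1)
print(f"gamma = {l1.params.gamma:.3f}, kappa = {l1.params.kappa:.2f}, "
      f"g = {l1.params.g:.2f}, tau = {l1.params.tau:.3f}")
print(f"L1 vs NS: chi2 = {chi2:.1f}, p = {p:.3g}")
```

prints (sampling noise at 10⁶ sites moves the estimates slightly):

```
gamma = 0.807, kappa = 2.27, g = 3.70, tau = 0.025
L1 vs NS: chi2 = 4049.2, p = 0
```

γ ≈ 0.79 means selection of strength 4N_e·s ≈ 0.8 favouring the focal
(major-codon) state, recovered from the spectrum together with a ~2.2-fold
mutational bias away from it, and the no-selection model is rejected
decisively.

The numbered scripts under `analysis/` run the whole study on a synthetic
chromosome (150 genes × 300 codons, 47 haplotypes over five arrangement
labels): `01_simulate.py` writes the dataset (under `scratch/sim/`),
`02_codon_bias.py` through `05_selection.py` write report tables under
`results/tables/` — major codons and G-tests, bias scores, composition,
diversity and region summaries, directional θ, Akashi ψ, model fits with
LRTs, and γ by Fop/ρ quartile. A `codonsel` command-line interface exposes
the same stages (`simulate`, `qc`, `bias`, `polymorphism`, `akashi`,
`selection`, `report`).

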