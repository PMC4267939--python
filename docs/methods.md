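# Methods

`codonsel` analyses per-gene haplotype alignments of protein-coding sequence
for codon usage bias and for selection acting on synonymous sites. This note
documents the models, the numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
more than one reasonable convention exists.

## Codon-level statistics

**Major codons.** The major codon of an amino acid is the most frequently
used synonymous codon in a pooled set of coding sequences; every other
synonymous codon is minor. Ties are resolved to the lexicographically
smallest codon and flagged (ties essentially never occur in genome-scale
counts). Heterogeneity of usage within a family is summarised by a G-test
against the equal-usage expectation E = total/k, with the convention
0·ln 0 = 0 and df = k − 1. The threefold family (Ile) is one class of 3,
and the sixfold families (Leu, Ser, Arg) are treated as single classes of
6 codons, not split 2+4. Codons containing N or alignment gaps are excluded
from every tally.

**ENC.** Wright's effective number of codons uses the per-family codon
homozygosity F̂ = (nΣp̂² − 1)/(n − 1) for families with n ≥ 2 observations,
averaged within each degeneracy class, ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆, clamped to [20, 61]. Wright's original leaves missing classes open;
here a missing threefold class is imputed as the mean of F̄₂ and F̄₄, and a
wholly missing 2/4/6 class drops its term with the remainder rescaled so
uniform usage still maps to 61. Families with F̂ ≤ 0 (possible at tiny n)
are excluded from the class average.

**Fop and CAI.** Fop is the fraction of major codons among codons of amino
acids that have a major codon (Met/Trp excluded); genes with no eligible
codon yield a missing value. CAI is the geometric mean of relative
adaptiveness weights w_c = f_c/max f within each family, computed from a
reference set. The default reference is the pooled usage of the top-decile
Fop genes of the input data (a self-contained proxy for a highly-expressed
reference set); codons unobserved in the reference receive a floor weight of
0.01 so the geometric mean stays finite.

**Composition randomization.** To ask whether amino-acid composition alone
explains a gene's bias, each replicate resamples every codon uniformly among
its family's synonymous codons — preserving the amino-acid sequence,
destroying preference — and the p-value is the fraction of replicates whose
ENC is at least as low (as biased) as observed. Genes with p > 0.05 are
flagged: their bias is explainable by composition and they are excluded from
selection analyses. The flag direction follows the "fraction of randomized
sequences as or more biased" reading; it is configurable because the
opposite reading ("significant effect of composition", p < 0.05) is also
defensible.

## Polymorphism

Synonymous and nonsynonymous site numbers follow Nei–Gojobori counting:
each codon position contributes (synonymous one-step changes)/3 synonymous
sites; mutations to stops count as nonsynonymous; totals sum to exactly 3
per codon. π_S is the mean number of pairwise synonymous differences per
synonymous site over all haplotype pairs — the pair average is the unbiased
(n/(n−1)-corrected) estimator — with per-pair denominators averaged over
the two sequences and ambiguous codons skipped. Watterson's θ is
S/(a_n·sites) with a_n = Σ_{i<n} 1/i, and Tajima's D uses the standard
constants. A differing position within a codon pair is counted synonymous
when the one-step exchange preserves the amino acid in both codon contexts.

Polarization takes the ancestral state to be the outgroup allele when it
matches one of the two segregating alleles; otherwise the site is
unpolarized and excluded from directional statistics. Preferred /
unpreferred labels apply only to synonymous, polarized, biallelic sites
whose two codons are the major and a minor codon of one amino acid
(derived major = preferred). Nonsynonymous polymorphisms are attributed to
the amino acid of the ancestral codon when polarized, else of the
majority-allele codon. Directional rates contrast polarized
third-codon-position changes: θ(GC→AT) counts GC→AT segregating sites per
ancestrally-G/C third position, and symmetrically for AT→GC. For a
reversible site at stationarity the count flux in the two directions is
equal, so the rate ratio estimates κ·e^(−γ); with γ = 0 it estimates the
mutational bias κ directly.

**SFS construction.** The site frequency spectrum is built over codon
columns: a column enters when its amino acid has a defined major codon and
it is either monomorphic (terminal classes 0/n) or segregates exactly one
major and one minor codon differing at a single nucleotide. Columns with
missing data, two minor codons, more than two codon states, multi-position
differences or amino-acid change are excluded, with per-reason counts kept.
Monomorphic classes are included because the model fits the mutation
parameters from them; spectra indexed by the major and by the minor codon
are exact mirrors. Sites with missing calls are excluded by default; a
hypergeometric projection to a common sample size is available.

## Akashi's translational-accuracy test

Conservation is classified at the amino-acid level per codon column:
conserved = ingroup amino acid monomorphic and equal to the outgroup's;
variable = ingroup amino-acid polymorphic; monomorphic-but-divergent
columns are excluded (ancestry is ambiguous there). A nucleotide-level mode
exists behind a flag. Per amino acid the 2×2 table counts
major/minor codons at conserved/variable columns over all haplotypes (so
sample size weights strata; a per-column majority mode is available), the
association is ψ = ad/bc, and strata pool by Mantel–Haenszel,
ψ_MH = Σ(a_k d_k/n_k)/Σ(b_k c_k/n_k), which tolerates zero cells without
continuity corrections (a Haldane–Anscombe +0.5 option exists for single
strata).

## The SFS selection model

Each site carries two alleles a₀/a₁ with scaled mutation rates
θ₀₁ = 4N_e μ₀₁ (a₀→a₁) and θ₁₀ = 4N_e μ₁₀, mutational bias κ = θ₁₀/θ₀₁,
and selection γ = 4N_e s on the focal allele a₁ (γ > 0 favours the focal
state; with the major-codon state focal, preferred spectra fit γ > 0 and
κ > 1, and the minor-codon spectra the mirror image). At equilibrium the
focal-allele frequency has Wright's stationary density
∝ x^(θ₀₁−1)(1−x)^(θ₁₀−1)e^(γx), and binomial sampling gives the closed-form
expected spectrum p_i ∝ C(n,i)·B(i+θ₀₁, n−i+θ₁₀)·₁F₁(i+θ₀₁; n+θ₀₁+θ₁₀; γ),
monomorphic classes included. The closed form is verified against adaptive
quadrature of the stationary density (QUADPACK with algebraic endpoint
weights) to relative error < 1e−6 in the test suite.

**One-step expansion (L1).** The population is at equilibrium, instantly
changes size by a factor g (scaled parameters become gθ₀₁, gθ₁₀, gγ), and
evolves for τ time units (units of 2N_e-after generations) before sampling.
The solver exploits diffusion duality: instead of evolving the singular
allele-frequency density, it evolves the n+1 smooth binomial sampling
kernels under the backward generator ∂u/∂t = ½x(1−x)u″ + M(x)u′ with
M(x) = ½[gγ·x(1−x) + gθ₀₁(1−x) − gθ₁₀x], then integrates them against the
*initial* equilibrium density using Gauss–Jacobi quadrature whose weight
function carries the x^(θ₀₁−1)(1−x)^(θ₁₀−1) boundary singularity exactly.
Time stepping is Crank–Nicolson on the boundary-clustered Gauss–Jacobi
node set (default 200 nodes, Δt ≤ 0.02, ≥ 16 steps), with first-order
upwinding of the drift where it dominates the vanishing diffusion near the
boundaries and one-sided pure-drift rows at x = 0, 1. Because the scheme
annihilates constants, probabilities sum to one by construction. g = 1 or
τ = 0 reduce analytically to the equilibrium form and are special-cased.

The solver is validated against an independent discrete Wright–Fisher
binomial-transition-matrix computation (2N = 400 haploids, rates rescaled,
exact stationary vector as the initial condition): total variation ≤ ~2e−3
across the tested parameter box (tolerance 5e−3). One caution: the
"τ → ∞ equals the rescaled equilibrium" limit is only reached on the
mutation timescale ~1/(g(θ₀₁+θ₁₀)), which for realistic θ is tens to
hundreds of time units; the limit test therefore runs at τ well beyond that
relaxation time, where the solver agrees with the rescaled closed form to
~2e−6 total variation.

**Likelihood and fitting.** The likelihood is multinomial over classes
0..n, lnL = Σ c_i ln p_i (a Poisson variant exists behind a flag); classes
with observations but zero probability give −∞. Models: L1 (θ₀₁, θ₁₀, γ,
g, τ), L0 (g = 1, τ dropped), NS (γ = 0), NS+L0. Fitting is multi-start
Nelder–Mead on [ln θ₀₁, ln θ₁₀, γ, ln g, ln τ] with box bounds enforced by
clip-plus-penalty; the objective is −lnL per site so tolerances are
independent of the number of sites. The first starts of L1/NS come from a
cheap equilibrium-model fit combined with a small (g, τ) grid — a
deterministic cascade that makes few starts reliable — and the remaining
starts are drawn log-uniformly from a seeded generator; the best run is
re-polished at tight tolerance. The library default is 50 starts;
self-consistency and recovery analyses use 4–8, which the cascade makes
sufficient (fits on expected spectra recover generating parameters to
~1e−6 relative). Nested models compare via χ² = 2(lnL_full − lnL_reduced).

**Binned fits.** Genes are split at type-7 quantile boundaries of a
covariate (Fop or ρ) into k equal-size bins, boundary ties going to the
lower bin; one pooled spectrum per bin is fitted and the 95% CI comes from
a multinomial bootstrap over sites (default 200 replicates; analyses here
use 100) refitted from the cascade start.

## Synthetic data

The generator emulates the study design: 47 haplotypes over five
arrangement labels (15/8/9/8/7), one close outgroup
(divergence 0.03 substitutions/site at synonymous positions), θ₀₁ = 0.005,
κ = 2.23, γ = 0.788 with a one-step expansion g = 3.70, τ = 0.026 as
defaults, per-gene selection classes available, and long-tailed per-gene ρ
(lognormal, mean 0.052/bp) over a 20-Mb chromosome with the outermost
inversion breakpoints at 2,496,966 and 17,725,256. For each codon column
one GC-ending favoured codon and its one-step AT-ending partner represent
the two-allele site; the favoured-codon count is drawn from the model's
expected spectrum at n+1, the extra lineage serving as the outgroup (this
gives polarization the correct joint distribution; additional outgroup
substitutions are applied at the configured divergence). Amino-acid
polymorphism is injected at a reduced θ (default 0.15× synonymous), and at
those variable columns synonymous selection is weakened by an accuracy
factor (default 0.5), which is what makes major codons preferentially
retained at conserved positions — the signal Akashi's test measures. A
small background-usage noise (1%) spreads counts over the remaining
synonymous codons.

Deliberately not emulated: linkage (sites are unlinked, as the analysis
model assumes — Hill–Robertson effects cannot arise in the generator),
ingroup fixed differences from the outgroup, indels, sequencing error, and
codon families used as more than two-state systems at a site. Passing
end-to-end tests therefore demonstrates internal consistency of the
estimators under the model's own assumptions, not robustness to linkage or
misalignment in real data.

Analysis scripts run at 150 genes × 300 codons with 100 bootstrap
replicates; the parameter-recovery and self-consistency checks use expected
spectra at 10⁶ sites. These problem sizes keep a full run to minutes while
leaving Monte-Carlo error well below the effect sizes examined.

## Known limitations

- Pooling genes with heterogeneous γ misspecifies the single-γ model: the
  pooled fit returns a usage-weighted compromise γ (and can distort the
  demographic parameters when the mixture is extreme), while per-class fits
  recover the generating values. Real-data estimates from pooled spectra
  inherit this caveat.
- Haplotype-level scatter that is not two-state at a site (e.g. sporadic
  use of a third synonymous codon, sequencing error) enters the spectrum as
  spurious singletons and biases the demographic parameters upward; the
  generator therefore keeps sites strictly two-state by default, and real
  data should be screened accordingly (the builder's exclusion log reports
  multi-state columns).
- Gene-level ψ_MH is noisy when a gene has only a handful of
  amino-acid-variable columns; pooled (class-level) Mantel–Haenszel
  contrasts are the stable summary at simulated polymorphism densities.
- The equilibrium closed form relies on SciPy's ₁F₁; it is accurate over
  the bounded γ range used here (|γ| ≤ 10) but not hardened for extreme
  arguments.
- G values reported with major-codon tables depend on absolute codon
  counts, so they are comparable only within a dataset.
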