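# Methods

## Model

A locus is a set of m SNPs with marginal association z-scores
`S = (s_1, …, s_m)` and pairwise correlation (LD) matrix `Σ`. Under the null
of no causal variant, `S ~ N(0, Σ)`: LD alone correlates the statistics.

Causal status is a binary vector `C ∈ {0,1}^m`. Conditional on `C`, true
(standardized, non-centrality-scale) effect sizes are `Λ | C ~ N(0, Δ)` with
`Δ = diag(d)`, `d_i = σ²` when `c_i = 1` and `d_i = ε` otherwise, and the
observed statistics follow `S | Λ ~ N(ΣΛ, Σ)`. Marginalizing Λ,

    S | C ~ N(0, Σ + Σ Δ Σ).

Causal indicators carry independent Bernoulli(γ) priors,
`p(C) = Π γ^{c_i} (1−γ)^{1−c_i}` (a per-SNP γ vector is also accepted). The
locus statistic is the likelihood ratio of "some causal configuration"
against the all-null configuration `C0`:

    LRT(S) = Σ_{C ∈ ζ, C ≠ C0} p(S|C) p(C)  /  [ p(S|C0) p(C0) ].

`ζ` is the enumeration set: all configurations with 1 to `max_causal` causal
SNPs among the `top_k` SNPs with largest |z| (ties broken by index; selection
is stable and the statistic is permutation-equivariant over the kept set).
Truncation is what keeps the enumeration tractable — with `top_k = 50` and
`max_causal ≤ 3` the set has at most 20,875 + 1 configurations.

## Parameters

| parameter | default | role |
|---|---|---|
| `gamma` | 0.01 | prior causal probability per SNP (scalar or length-m vector) |
| `sigma2` | 27.04 | prior effect-size variance of a causal SNP (= 5.2², a non-centrality of ≈5.2, i.e. a clearly genome-wide-significant single-SNP signal) |
| `epsilon` | 0 | residual effect variance of non-causal SNPs; must be < `sigma2` |
| `max_causal` | 3 | largest causal count enumerated (2 is materially faster and nearly as powerful at small loci) |
| `top_k` | 50 | truncation: SNPs kept by \|z\| before enumeration |
| `ridge` | 1e-6 | diagonal inflation applied (with a RuntimeWarning) when Σ's smallest eigenvalue is below 1e-8, e.g. duplicated SNPs |

## Evaluation of the likelihoods

`Σ + ΣΔΣ` differs from `Σ` by a rank-`n_causal` update (plus, for ε > 0, an
isotropic-in-Σ part). Writing `E` for the causal-column selector and using
`Σ⁻¹(ΣE) = E`, the quadratic form and log-determinant reduce to

    log|Σ + ΣΔΣ| = log|Σ_ε| + log|I + d · B_cc|,
    Sᵀ(Σ + ΣΔΣ)⁻¹S = q₀ − T_cᵀ (I/d + B_cc)⁻¹ T_c,

where for ε > 0, `A = (I + εΣ)⁻¹`, `B = ΣA`, `T = AS`, `d = σ² − ε`, and
`q₀ = SᵀΣ_ε⁻¹S`; for ε = 0 these collapse to `B = Σ`, `T = S`. Only one
Cholesky factorization of `Σ` is taken per locus; each configuration then
costs `O(n_causal³)`. Configurations of equal causal count are evaluated in
batches with stacked `slogdet`/`inv` and einsum contractions, chunked to
bound memory, and the `K × |ζ|` log-likelihood sums are accumulated with
log-sum-exp. Exact equivalence with dense multivariate-normal evaluation is
asserted in the test suite at 1e-8 relative tolerance over random loci.

The returned `lrt_stat = exp(log_l1 − log_l0)` may overflow to `+inf` for
very strong signals; this is deliberate (the log parts stay finite and all
comparisons against thresholds remain correct). A `NumericalError` is raised
only when a log-likelihood itself is non-finite or a configuration covariance
is not positive definite (the error names the offending index set).

## Null panels and empirical significance

Three samplers produce null statistics `S ~ N(0, Σ)`:

1. **Direct**: Cholesky of Σ applied to standard normals.
2. **Genotype trick**: with standardized genotypes `X` (n × m, `XᵀX/n = Σ`),
   `S = Xᵀ s*/√n` for `s* ~ N(0, I_n)` has exactly the target law — no m×m
   factorization and the empirical, possibly rank-deficient LD is honoured.
3. **Importance sampling**: draws from a heavier proposal with covariance
   `c·Σ` (default `c = √2`) and weights
   `W = f(S; 0, Σ) / f(S; 0, cΣ)` evaluated at the proposal draw, so
   `E[W] = 1`. When only Σ is available the draw is taken in m-space
   (`S ~ N(0, cΣ)`, `log W = (m/2)log c − (1 − 1/c)·SᵀΣ⁻¹S/2`), which is the
   exact marginalization of the n-space scheme and yields the identical
   weighted estimator. An n-space routine is provided for use with genotypes.

A panel stores K null LRTs, weights (all 1 for unweighted samplers), and the
per-draw univariate p-values `2Φ(−max_i |s_i|)`, together with the LD
checksum, seed and model parameters; panels round-trip losslessly through
TSV + JSON sidecar.

Given observed `LRT_data`:

- empirical p-value: `p = Σ_{LRT_i > LRT_data} W_i / Σ W_i` (strict
  exceedance; a weighted mean over the null panel);
- significance threshold at per-test level α: the set-test p corresponding to
  the univariate tail, `p_thr = Σ_{uni_p_i < α} W_i / Σ W_i`; the locus is
  significant when `p < p_thr` (importance panels) or `p < α` (direct
  panels, where p itself is on the α scale);
- the panel's resolution (smallest nonzero p it can report,
  `min W / Σ W`) is attached so a reported 0 can be read as "< resolution".

Importance sampling exists because direct estimation of genome-wide tails
(α ≈ 5e-8) needs ~10⁸ draws; a 10⁴-draw importance panel estimates the same
tail probabilities, at the cost of weight-variance-driven error that the
tests bound against a large direct panel.

## Calibration, type-I error and power

`calibrate_threshold` transfers a univariate significance level to the LRT
scale on a shared null panel: with `q = #{uni_p < α}` null replicates
univariately significant, the LRT threshold is the q-th largest null LRT
(exactly q null LRTs are ≥ it; a `CalibrationError` is raised when q = 0).
Power is the percentage of alternative replicates with `LRT > threshold`
(strict; alternatives are continuous so the convention is almost surely
irrelevant). The relative improvement reported is
`(P_set − P_uni)/P_uni × 100`.

The type-I experiment is split-half: the LRT threshold is the upper-α order
statistic of the first half of a null panel taken directly, and the false
positive rate is the exceedance fraction of the second half. The acceptance
suite checks it against the nominal level within 3 binomial standard errors
at α = 5e-2 and 5e-3.

## Synthetic data generators — scope

The simulation module emulates the statistical structure of a locus, not a
population-genetic history:

- `gen_ld` produces AR(1) (`Σ_ij = ρ^|i−j|`) or block-constant correlation
  matrices — stylized LD, not coalescent LD.
- `gen_genotypes` draws dosages in {0,1,2} by thresholding a latent MVN at
  Hardy–Weinberg genotype-frequency quantiles; realized LD approximates the
  target (attenuated by discretization) and there is no mutation, selection
  or relatedness.
- `genotypes_from_ld` builds a synthetic real-valued genotype matrix with
  *exactly* `XᵀX/n = Σ` (orthonormal columns orthogonal to the intercept,
  rotated onto `chol(Σ)`); it is for exercising the genotype-trick sampler,
  not a genotype model.
- Alternative summary statistics are drawn from their marginal law
  `S ~ N(ΣΛ, Σ)` directly (with fixed or randomly placed causal sets); an
  end-to-end test confirms this matches z-scores obtained by actually
  regressing simulated phenotypes on simulated genotypes.

## Problem sizes

Experiments packaged in `scripts/acceptance.py` and the test suite run at
desk scale: loci of m = 10–50 SNPs, 10⁴–10⁵ replicates, significance levels
1e-5 to 5e-2, `max_causal = 2` for the heavy loops. A 10⁵-draw panel with
|ζ| = 210 configurations evaluates in ~2 s on one core.

## Known limitations

- **Power saturation compresses relative improvement.** At small loci and
  lenient levels, adding causal variants drives both the set test and the
  univariate baseline toward 100% power, so the *relative* improvement can
  shrink as causal count grows even while absolute power dominance holds
  (measured at m = 20, λ = 4.5, α = 1e-5: improvement ≈ 5% with 2 causals
  vs ≈ 1.8% with 3, with univariate power already ≈ 97% in the 3-causal
  design). Separating the regimes requires genome-wide levels (~5e-8),
  correspondingly huge null panels, and larger/realistic loci. The
  acceptance script reports both the 2- and 3-causal powers so this is
  visible rather than hidden.
- Truncation to `top_k` makes the statistic depend on the selected subset;
  for loci with many comparable signals beyond the cut the statistic is a
  lower bound on the untruncated one.
- `ε ≥ σ²` is rejected; ε > 0 adds one extra m×m solve per locus.
- Importance-panel p-values inherit weight variance; the stored resolution
  and the ratio-estimator standard error (see tests) should be consulted
  before trusting extreme tails.
- Empirical LD from finite reference panels is noisy; the test assumes Σ is
  the covariance of S. Ridge regularization guards singularity, not panel
  mismatch — the LD checksum guards against using a panel built on different
  variants, not against a wrong reference population.
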