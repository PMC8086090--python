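# mars-assoc

A model-based set association test for GWAS and eQTL loci. Given per-SNP
summary statistics (z-scores) and the linkage-disequilibrium (LD) matrix of a
locus, the test aggregates evidence over every possible configuration of
causal variants instead of looking only at the single strongest SNP, and
assesses significance by resampling. It is aimed at statistical geneticists
who want a locus-level (gene-level) test that gains power when a locus
harbours more than one causal variant in LD.

## The statistic

Let `S = (s_1, …, s_m)` be the marginal z-scores of a locus and `Σ` the SNP
correlation matrix, which is also the covariance of `S`. For a binary causal
status `C` (with at most `max_causal` ones), effect sizes are
`Λ | C ~ N(0, Δ)` with `Δ_ii = σ²` for causal SNPs (and `ε`, default 0,
otherwise), and `S | Λ ~ N(ΣΛ, Σ)`, so that

    S | C ~ N(0, Σ + ΣΔΣ).

With independent Bernoulli(γ) priors on the causal indicators (γ = 0.01 by
default), the locus statistic is the likelihood ratio

    LRT = Σ_{C ≠ C0} p(S|C) p(C)  /  [ p(S|C0) p(C0) ],

summing over all statuses with 1..`max_causal` causal SNPs among the top-`k`
SNPs by |z| (k = 50 by default). Each configuration's covariance is a low-rank
update of `Σ`, so the likelihood is evaluated with the Woodbury identity and
the matrix-determinant lemma at `O(n_causal³)` per configuration after one
factorization per locus; all sums are accumulated in log space.

Significance is empirical: the observed LRT is compared against a panel of K
null LRTs computed on draws from `S ~ N(0, Σ)`. Panels can be drawn directly
(Cholesky), through a genotype trick (`S = Xᵀs*/√n`, `s* ~ N(0, I_n)`) that
never factors an m×m matrix, or with importance sampling from a
heavier-tailed proposal (covariance `√2·Σ`) whose density-ratio weights make
genome-wide tail p-values estimable from ~10⁴ draws instead of ~10⁸.

## Worked example

Simulate a 50-SNP AR(1) locus (ρ = 0.6) with two causal variants of
non-centrality λ = 5 implanted, write its z-score table and LD matrix, then
build an importance-sampled null panel and test the locus:

```python
import numpy as np, pandas as pd, mars
from mars import io as mio

ld = mars.gen_ld(50, "ar1", 0.6)
alt = mars.AltSpec(m=50, causal_indices=[12, 33], lam=5.0)
z = mars.sample_alt_stats(ld, alt, 1, seed=4)[0]
mio.write_zscores(pd.DataFrame({"snp_id": [f"rs{i}" for i in range(50)], "z": z}), "z.tsv")
mio.write_ld(ld, "L.mat")
```

```sh
$ mars panel --ld L.mat --K 10000 --seed 1 --max-causal 2 --importance --out panel.tsv
wrote 10000-draw importance panel to panel.tsv
$ mars test --zscores z.tsv --ld L.mat --panel panel.tsv --alpha 1e-5 --max-causal 2
{
  "lrt_stat": 7313603.650914249,
  "p_value": 0.0,
  "p_threshold": 0.00048355467264911287,
  "significant": true,
  "method": "importance",
  "m_used": 50
}
```

`lrt_stat` is the prior-weighted likelihood ratio of the locus; `p_value` is
the weighted fraction of null panel LRTs exceeding it (0 here: no null draw
comes close); `p_threshold` is the locus-level empirical p corresponding to
the per-test level 1e-5, obtained by the weighted univariate-quantile
transfer; the locus is called significant because `p_value < p_threshold`.

A power experiment against the univariate max-|z| baseline (two causal SNPs,
λ = 4.5, 20-SNP AR(1) ρ = 0.5 locus, 10⁵ replicates, level 1e-5):

```sh
$ mars simulate --m 20 --causals 2 --lambda 4.5 --reps 100000 --alpha 1e-5 --seed 7 --max-causal 2
{
  "power_mars": 89.417,
  "power_uni": 84.974,
  "improvement_pct": 5.228658177795558,
  ...
}
```

The set test rejects 89.4% of alternative replicates against 85.0% for the
univariate test at the same calibrated locus-level false-positive count — a
5.2% relative power improvement.

Other subcommands: `mars calibrate` (threshold transfer of a stored panel)
and `mars scan` (multi-gene scan with TSS-window locus assembly and null-panel
caching/reuse keyed by an LD checksum). Everything the CLI does is a thin
wrapper over the `mars` library API.

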