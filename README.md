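# locusrisk

Bayesian prioritization of risk genes at GWAS loci from multi-omics
evidence and gene networks.

Genome-wide association studies report index SNPs, not genes: the causal
gene at a locus is frequently *not* the one nearest the lead SNP, and a
±1 Mb window around an index SNP typically contains on the order of ten
candidates. `locusrisk` ranks those candidates by combining two sources of
information:

1. **Per-gene multi-omics evidence** — a mix of p-value features
   (differential expression, de novo mutation burden, gross deletions) and
   continuous features (distance to the index SNP, regulatory-element
   counts, expression levels).
2. **Gene–gene networks** — the premise that true risk genes at different
   loci tend to interact with each other (protein–protein interaction,
   ontology-similarity, or tissue-specific networks).

## The model

Let `L` loci each contribute a candidate set, and let `X_l` be the gene
selected at locus `l`. The joint posterior over selections factorizes as

    P(X_1, …, X_L | D, N) = ∏_l P(X_l | X_{-l}, N) · P(D_l | X_l)

where `D` are the per-gene features and `N` the networks.

* `P(X_l | X_{-l}, N)` is a **network prior**: the random-walk-with-restart
  (restart probability `r = 0.5`) steady-state probability of candidate
  `X_l` when the walk restarts uniformly from the genes currently selected
  at the other loci, floored and renormalized over the locus's candidates,
  averaged across networks.
* `P(D_l | X_l)` is an **evidence score**: continuous features are
  decorrelated with the Hotelling transform (projection on the covariance
  eigenvectors), each retained component is made near-Gaussian by a fitted
  Box–Cox power transform and converted to an upper-tail normal p-value,
  and all p-values — transformed and raw — are combined by Fisher's method
  (χ² with 2(n+n′) df). The score is −ln of the combined p-value.

Because enumerating all gene combinations is infeasible, the posterior is
sampled by **Gibbs sampling**, one locus at a time, in two cycles (the
second restarts from the first's final state). A cycle stops when the
Euclidean norm of the change in the selection-frequency vector between
sweeps drops below `E_Gibbs = 0.01`. The posterior probability (PP) of a
gene is its selection frequency in the second cycle; the **HRG**
(high-risk gene) of a locus is its maximum-PP candidate, and **LBGs**
(low-risk background genes) are genes whose merged PP falls strictly below
the median over all candidates.

## Worked example

Generate a synthetic benchmark with planted risk genes (strong signal:
planted p-values ~ Beta(0.2, 1), continuous features shifted by 1.5 sd,
planted genes forming a dense network module), fit, and score recovery:

```python
from locusrisk.simulate import SyntheticConfig, generate_instance, score_recovery
from locusrisk.model import RiskGeneModel

cfg = SyntheticConfig(n_loci=20, candidates_per_locus=10, planted_effect=1.5,
                      pvalue_signal=0.2, module_within_weight=0.8,
                      background_weight=0.05, seed=3)
locus_map, features, networks, truth = generate_instance(cfg)
results = RiskGeneModel(locus_map, features, networks).fit(seed=11)
print(results.summary())
print("planted-gene recovery:", score_recovery(truth, results.posterior))
```

Output:

```
Risk-gene prioritization results
========================================
loci (non-empty):        20
candidate genes:         200
networks:                2
seed:                    11
sweeps (cycle1, cycle2): (188, 181)
converged:               True
HRGs called:             20
LBGs called:             93
median HRG PP:           0.834
mean HRG PP:             0.793
planted-gene recovery: 1.0
```

Each of the 20 loci receives exactly one HRG call; here every HRG is the
planted gene, with a median posterior probability of 0.83. The 93 LBGs are
the candidates falling below the median PP. `results.posterior` carries the
full per-locus PP table, `results.hrg_frame()` a per-locus report with
SNP distances and nearest-gene flags, and `results.save(out_dir)` writes
`posterior.tsv`, `hrgs.tsv`, `lbgs.tsv` and `ranked.tsv`.

The same pipeline is available from the shell:

```bash
locusrisk simulate --planted-effect 1.5 --pvalue-signal 0.2 \
    --module-within-weight 0.8 --seed 3 --out sim/
locusrisk run --loci sim/loci.tsv --genes sim/genes.bed \
    --features sim/features.tsv --network sim/net_module.tsv \
    --network sim/net_noise.tsv \
    --pvalue-cols pval_0,pval_1,pval_2 \
    --continuous-cols cont_0,cont_1,cont_2,cont_3 \
    --seed 11 --out out/
locusrisk evaluate --posterior out/posterior.tsv --gene-sets sets.gmt \
    --universe-size 20000 --out eval/
```

`evaluate` computes one-sided Fisher's exact enrichment of HRGs against
LBGs over supplied gene sets (Bonferroni-corrected) and binomial overlap
tests against an external-universe size.

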