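# Methods

This note documents the model implemented by `locusrisk`, the numerical
choices made where the design was genuinely open, what the synthetic
benchmark does and does not emulate, and known limitations.

## Model

One candidate gene `X_l` is selected per GWAS locus; the joint posterior
over selections factorizes into, per locus, a network term times an
evidence term:

    P(X_1, …, X_L | D, N) = ∏_l P(X_l | X_{-l}, N) · P(D_l | X_l)

The sampler never needs the joint normalizer: Gibbs sampling only requires
each locus's conditional, which is the (network prior × evidence) product
normalized over that locus's candidates.

### Candidate mapping

A gene is a candidate of a locus when its interval intersects the closed
window `[pos − W, pos + W]` around the index SNP, `W = 1 Mb` per side.
Genes use BED 0-based half-open coordinates, SNPs 1-based positions
(converted to 0-based before comparison). Boundary-touching genes count:
"within 1 Mb" is read inclusively, the more permissive choice. Loci with
no genes are retained (flagged) so locus counts stay aligned with the
input SNP table; a gene may belong to several overlapping loci.

The distance-to-SNP feature is measured to the nearer interval coordinate
(start or half-open end), 0 inside the gene body. This requires no strand
assumption; a strand-aware TSS mode (`distance_mode: tss`) is provided
because either convention is defensible.

### Evidence integration

Continuous features (g × m matrix P):

1. **Hotelling transform** — center columns, project onto the
   eigenvectors of the sample covariance (denominator g − 1). Components
   are sign-oriented so each one's largest-magnitude loading is positive;
   eigenvector signs are otherwise arbitrary and would make the
   subsequent one-sided tail meaningless. `n_components="auto"` retains
   components with eigenvalue above 1e-10 × the leading eigenvalue,
   i.e. drops numerically null directions only.
2. **Box–Cox transform** per component — the component is shifted by
   `c = 1 − min(x)` when any value is non-positive (so the shifted
   minimum is 1), and the exponent β maximizing the profile
   log-likelihood is found by golden-section search on [−5, 5] with
   tolerance 1e-5. |β| < 1e-8 falls back to the log branch.
3. **Gaussian p-values** — each transformed component is standardized
   (sample sd, g − 1) and mapped through the upper-tail standard-normal
   survival function; a two-sided option exists but the upper tail is the
   default because downstream treats small p as risk evidence.
4. **Fisher's combination** — the component p-values and the gene's raw
   p-value features are pooled: T = −2 Σ ln p is referred to the χ²
   survival function with 2(n + n′) degrees of freedom, the standard
   form of Fisher's combined probability test. The per-gene evidence
   score is −ln(combined p), non-negative and increasing in signal.
   All p-values are clamped to [1e-300, 1] to keep the logs finite.

Missing data: continuous cells are imputed with the per-column median and
missing p-values as 1.0 (no evidence); every imputation is counted in the
log so users can audit the fill-in.

### Network prior

Each network is column-normalized by weighted degree into a
column-stochastic matrix W; universe genes absent from the network (and
zero-degree nodes) receive a unit self-loop column so W stays stochastic
without discarding genes. The random walk with restart iterates
`p ← (1−r)·W·p + r·e` (restart probability r = 0.5 by default, tolerance
1e-10), equivalently the linear solve `p = r(I − (1−r)W)⁻¹e`. Inside the
sampler the dense resolvent kernel is precomputed once per network, so
each conditional is a column-mean lookup rather than an iterative solve;
both routes agree to solver tolerance and are cross-checked in the tests.

For locus `l`, the restart vector is uniform over the genes currently
selected at the other loci, restricted to genes the network actually
contains. The candidates' steady-state probabilities get a floor of
`floor_eps = 1e-6` (preventing zero conditionals that would freeze the
chain) and are renormalized over the locus. Multiple networks are combined
by the arithmetic mean of the per-network normalized vectors (a product
rule is available via `combine: product`). With no usable restart genes
the prior is uniform.

### Gibbs sampling

Two cycles. Cycle 1 initializes each locus uniformly at random; cycle 2
restarts from cycle 1's final selection, so cycle 1 acts as burn-in /
initialization refinement and PP is taken from cycle 2 only (a pooled
option exists). Loci are visited in fixed input order (systematic scan;
random scan available). Counts and the frequency vector Freq are updated
after every individual sampling; after each sweep the cycle stops when
`‖Freq_i − Freq_{i−1}‖₂ < E_Gibbs = 0.01`, with `min_sweeps = 10` to
prevent spurious convergence while frequency vectors are still sparse and
`max_sweeps = 5000` as a hard cap (hit ⇒ warning, not an error). The
frequency denominator is the number of samplings of that gene's own
locus, so per-locus frequencies are comparable and sum to one.

Genes belonging to several loci get a merged PP equal to the maximum over
their loci (per-locus values are kept too). HRG = per-locus argmax PP
(symbol tie-break, logged); LBG = merged PP strictly below the median of
all candidates' merged PPs. A gene meeting both definitions keeps the HRG
label and the collision is logged. The top-10% report returns
`ceil(0.1·g)` genes by descending merged PP.

## Synthetic benchmark

`locusrisk.simulate` generates instances with known truth: loci spaced
10 Mb apart on one synthetic chromosome, each window holding exactly
`candidates_per_locus` genes (10 kb genes, evenly spaced); one planted
risk gene per locus. Planted genes draw p-value features from Beta(a, 1)
(`a = pvalue_signal`; a = 1 is the uniform null, smaller a concentrates
near 0, mean a/(a+1)), continuous features are standard normal with the
planted genes shifted by `planted_effect` sd, and two networks are
produced: a planted-partition graph in which planted genes interconnect
with probability `module_within_weight` against `background_weight`
elsewhere, and a pure-noise graph, so multi-network combination is
exercised. The default condition (20 loci × 10 candidates,
`planted_effect = 0`, `pvalue_signal = 1`, equal block weights 0.05) is
the exchangeable null; the benchmark grid used by the tests and
`scripts/acceptance.py` adds a moderate (0.7 sd, a = 0.5, module 0.3) and
a strong (1.5 sd, a = 0.2, module 0.8) condition, each averaged over
replicate seeds. Problem sizes (20 loci, 10 candidates, 10–20 replicates)
were chosen as the smallest instances at which chance level (10%) and
strong recovery separate cleanly.

What the generator does **not** emulate: linkage-disequilibrium structure
(loci are independent and non-overlapping by construction), realistic
expression or distance distributions (features are Gaussian/uniform), and
scale-free network topology. Passing tests therefore demonstrate the
correctness and calibration of the machinery — not field performance on
real GWAS data, where feature informativeness and network quality
dominate.

A note on the null: a null *instance* is exchangeable across candidates —
no gene is favored in distribution — but any single realization still has
random feature noise, so per-gene evidence varies and individual PPs
legitimately deviate from 1/k. Exact PP uniformity (every PP within
Monte-Carlo error of 1/k) holds only under *flat* evidence and a
symmetric prior, and that is how the sampler's symmetry is tested;
exchangeability of the full pipeline is tested as recovery of the
arbitrary planted labels at the 1/k chance rate across replicate seeds.

## Numerical choices and degenerate inputs

- p-value clamp floor 1e-300 (keeps −ln finite); evidence floor 1e-6 for
  genes with zero score, so conditional weights are strictly positive.
- Constant vectors: Box–Cox fitting and standardization raise a
  degenerate-data error; exactly collinear continuous features are
  handled by the auto component cut.
- Requesting more components than the covariance rank is an error;
  "auto" never selects zero components.
- Duplicate network edges merge by maximum weight; self-loops are dropped
  on input (the propagation kernel adds its own for dangling columns);
  both events are counted in the log.
- Ties everywhere break lexicographically by gene symbol, making every
  output deterministic given the seed.
- The permutation interaction test uses the add-one empirical p
  (never exactly 0); an exhaustive enumeration mode exists for small
  complements. The false-positive-rate curve's negative-set draws default
  to desk scale (configurable count).

## Limitations

- The RWR variant (normalization, r, restart set, multi-network
  combination rule) follows documented defaults chosen from the
  conventions of this method family; alternatives are config switches,
  and results can be sensitive to them on sparse networks.
- Eq.-level ambiguities in the source method family (degrees of freedom
  of the combination test, which normal tail, whether PP pools both
  cycles) are resolved as documented above and exposed in config rather
  than asserted as the original authors' behavior.
- One HRG per locus is the calling rule; selecting multiple risk genes
  per locus is only supported through the top-fraction ranking.
- Heritability enrichment, tissue/cell-type specificity analyses and
  external-database comparisons require external data resources and are
  out of scope; the enrichment/overlap/permutation/FPR machinery they
  would feed is implemented and tested.
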