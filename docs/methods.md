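# Methods

## Model and procedure

`diffconn` operationalises differential connectivity for a two-group
(control vs AMI), two-cohort (discovery, validation) expression study.
All analysis stages are deterministic; the only randomness in the
package lives in the synthetic-study generator.

### DEG cascade

The screen is a fixed-order cascade per gene:

1. two-sample Kolmogorov–Smirnov at α₁ — a distribution-shape
   difference alone is sufficient evidence of differential expression;
2. Shapiro–Wilk normality per group at α₂ (a constant group counts as
   maximally non-normal);
3. if both groups pass normality: median-centred Levene at α₃ decides
   between Student's *t* (homogeneous variances) and Welch's *t*;
4. otherwise the two-sided Mann–Whitney rank-sum test.  The final
   location test runs at α₄.

All tests are two-sided and no multiplicity correction is applied; the
stringent defaults (α₁ = 10⁻⁵, α₂ = 2·10⁻⁵, α₃ = α₄ = 10⁻⁵) already
hold the family-wise null expectation below one gene at panel sizes of
~2·10⁴.  The concrete tests behind "shape", "normality" and "variance
homogeneity" are this package's choices of standard instruments; other
reasonable substitutions (Anderson–Darling, Brown–Forsythe on means)
would shift individual branch routings but not the calibration
properties the test suite asserts.  Note the cascade is not formally
monotone in the α vector: shrinking α₂/α₃ can reroute a gene between
the rank-sum and *t* branches, whose p-values differ.  Empirically, on
null data at these levels, tightening every α never adds a call, and
that is the property the suite checks.

A location shift large enough to reject the KS test is recorded as a
"shape" difference even though it is not a shape change in the casual
sense; the cascade is applied literally.

### Networks and clustering coefficients

Pearson correlation is computed per group over the DEG set; an edge
requires |r| strictly above the threshold.  Zero-variance genes get
r = 0 (isolated) and a log entry instead of an exception, so degenerate
synthetic inputs cannot poison a run.  The clustering coefficient
C_i = 2E_i/[k_i(k_i − 1)] is implemented directly from the adjacency
sets, with C_i = 0 for k_i ≤ 1 (the formula is undefined there; zero is
the standard convention and keeps averages well-defined).  The
"clustered gene" count at a threshold is the number of genes with
C_i > 0, i.e. genes participating in at least one triangle; a
connected-component count (components of size ≥ 2) is exported for
comparison but is not the headline statistic, because component counts
cannot fall as steeply as triangle membership when edges are removed.

### Separation and scale-freeness

For the DEG set, the per-threshold gap is
avg C_i(AMI) − avg C_i(control), averages taken over *all* DEGs
including isolated ones.  A threshold is separable when the gap is
positive; the *average separable width* is the mean gap over separable
thresholds and the *separable range* is the longest contiguous run of
them.  This is the simplest statistic consistent with reporting a
single per-cohort width; no uncertainty is attached to it.

Power-law exponents are estimated, by default, with least squares on
log frequency vs log degree over the non-empty histogram bins of
positive degrees, refusing to fit fewer than three distinct degrees.
This estimator is exact on noiseless histograms but is known to be
flattened by singleton bins in heavy tails (on preferential-attachment
graphs with true exponent 3 it reads ≈ 1.9 at n = 2000).  A
zeta-normalised discrete maximum-likelihood estimator is available as
`method="mle"` and is the right choice when the estimate itself
matters; the regression default is retained for its transparency and
exactness on clean histograms.

### DCG calling and hubs

The band mean of C_i over thresholds {0.4, 0.5, 0.6, 0.7, 0.8} (five
values, arithmetic mean) summarises one gene × group × cohort.
Candidates must exceed a cc-difference of 0.1 (strict) in discovery AND
validation; DCGs must additionally exceed it in the pooled combination
cohort.  The connectivity fold-change divides AMI by control band means
with the denominator clamped at ε = 0.01 (and flagged): published
fold-changes are large but finite, implying nonzero control means, so ε
only matters for degenerate synthetic cases.  Expression change is the
difference of group means on the log2 scale — i.e. a log2 fold-change —
which is the reading under which "fold-changes" of ~0.4 coexist with
genes described as upregulated.  The 2-D classification uses strict
cutoffs (fold-change > 2, expression change > 0.4); hub genes are the
CC^high GeExp^high DCGs, clusters are hub ego-networks in the AMI-group
DCG subnetwork at thresholds 0.5 and 0.7, and a DCG adjacent to two or
more hubs is a bridge.  Fold-changes and the classification are taken
from the discovery cohort (the better-calibrated dataset in the
motivating study); cluster extraction uses the combination cohort's AMI
samples, which give the tightest correlation estimates.

## Synthetic studies

The generator draws log2 intensities from multivariate normals:
gene-wise mean `baseline_log2` (default 8.0, a typical normalised
microarray intensity), correlation matrix per group scaled by
`noise_sd`.  Hub blocks are compound-symmetric: every within-block pair
has correlation `rho_control` (control) or `rho_ami` (AMI).  Mean
shifts of `delta_log2` are applied in the AMI group to the block genes
and to `n_deg_shift` uncorrelated "decoy" genes, which are
differentially expressed but not differentially connected — the
realistic negative class for DCG calling.

Two blocks that declare a shared (bridge) gene are coupled: their
cross-block correlation is set to rho_A·rho_B, the value implied by
conditional independence of the blocks given the bridge.  This is not a
convenience: a gene cannot be correlated at 0.8 with two mutually
uncorrelated cliques (the resulting matrix has negative eigenvalues),
so sharing a member mathematically forces the cliques to co-vary.  Any
remaining non-PSD request (e.g. a block forced to be less correlated
internally than a strong shared background) is rejected at construction
with the offending blocks named; nothing is silently repaired.

One study seed deterministically spawns an independent stream per
cohort (`SeedSequence([seed, cohort_index])`), so cohorts are
independent draws, a single cohort is reproducible in isolation, and
byte-identical TSVs come out of repeated runs.

The default recovery conditions are: 300 genes, 20 decoy DEGs, two hub
blocks of a designated hub plus 8 members sharing one bridge gene (17
planted genes), rho_control = 0.1, rho_ami = 0.8, delta_log2 = 1.0,
noise_sd = 0.5, background correlation 0.05, cohorts of 22/21 and 28/28
samples.  The panel size of 300 keeps a full multi-seed recovery
experiment in the order of seconds per run while leaving the null class
two orders of magnitude larger than the planted class.  Because all
block genes are exchangeable under compound symmetry, every planted
block gene — not just the designated centre — tends to be classified
CC^high GeExp^high end-to-end; hub designation is only distinctive in
data whose blocks have internal structure (e.g. real regulatory
modules).

Recovery sensitivity under these conditions is dominated by the DEG
screen, not by the connectivity stage: a planted gene that reaches the
network step is essentially always confirmed as a DCG.  Because block
genes share a latent factor, their test statistics are correlated, and
an unlucky factor draw can push much of a block below the stringent α
together — multi-seed sensitivity therefore fluctuates more than a
per-gene power calculation suggests, which is why recovery is always
reported over batches of seeds.

What the generator does *not* emulate: probe-level structure, batch or
cohort effects, non-Gaussian heavy-tailed intensities, correlated null
background beyond exchangeable weak correlation, and missing values.
Passing recovery tests therefore demonstrates the pipeline's logic and
calibration, not robustness to microarray artefacts.

## Numerical choices and degenerate inputs

- Strict inequalities throughout (|r| > x, cc-diff > 0.1, fold-change
  cutoffs): ties at a boundary are classified "low"/absent.
- Genes constant in both groups yield a degenerate non-DEG decision
  (p = 1) rather than an error; a gene constant in one group routes to
  the rank-sum branch.
- Correlations are clipped to [−1, 1] post-computation to absorb
  floating-point overshoot.
- PSD validation uses an eigenvalue floor of −10⁻⁸ on the requested
  correlation matrix; Cholesky factorisation then requires strict
  positive-definiteness (guaranteed by rho < 1 in practice).
- Written tables use 6 significant digits; reread-and-rewrite is
  byte-stable, which is what the determinism tests assert.

## Problem sizes used by the test and acceptance runs

Recovery and null experiments run 20 seeds in the test suite and 10 in
the acceptance script at the default conditions above; DEG calibration
uses 10,000 null genes at 22/21 samples; graph oracles cover all 64
graphs on 4 nodes, 200 random graphs on 5–8 nodes and 100 on up to 30
nodes; Erdős–Rényi checks use G(30, p) with 50 replicates.  These sizes
were chosen to give stable Monte-Carlo margins (≥ 3 standard errors)
at interactive runtimes.

## Known limitations

- The cascade's branch choices stand in for an unspecified family of
  shape/normality/variance instruments; calibration, not branch
  identity, is the tested contract.
- The separable-width statistic has no published closed definition to
  compare against; ours (mean positive gap) is declared, not derived.
- The regression power-law estimator is biased on heavy tails (see
  above); use the MLE for quantitative exponent claims.
- Real-data headline counts depend on probe-to-gene collapsing and the
  assignment of samples to cohorts, neither of which this package
  prescribes; `read_geo_series_matrix` deliberately returns probe-level
  data and leaves collapsing to the caller.
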