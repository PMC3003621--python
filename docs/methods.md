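# Methods

## Model

`jointeb` fits a two-platform hierarchical Gaussian model to probe-level
log2 intensities. Per gene *i*, condition *l* ∈ {1, 2}:

```
expression   G_ijkl = mu_il + b_ij + eps_ijkl     j = 1..J_i probes, k = 1..K replicates
methylation  M_ihl  = eta_il + a_ih + d_ihl       h = 1..H_i probes, single measurement
b_ij ~ N(0, sigma2)   eps_ijkl ~ N(0, delta2)
a_ih ~ N(0, omega2)   d_ihl    ~ N(0, tau2)
(mu_i1, mu_i2, eta_i1, eta_i2)' ~ N(mu, Sigma)
```

Sigma is a free symmetric PSD 4×4: expression block Sigma_1, methylation
block Sigma_2, and an unconstrained 2×2 cross block that lets the model
borrow strength between platforms and carry a genuine across-gene
coupling of expression and methylation levels. Probe effects are random
and shared by all measurements of a probe; this induces positive
correlation between measurements of the same probe and (through Sigma)
dependence between the platforms.

Stacking one gene's data as `D = Delta beta + eps` with
`beta = (mu_i1, mu_i2, eta_i1, eta_i2, b_1..b_J, a_1..a_H)` makes the
block conjugate: `beta | D` is normal with precision
`Delta' Se^-1 Delta + Sp^-1` (Se diagonal, Sp block-diagonal). All
posterior computations use Cholesky solves of this small
(4+J+H)-dimensional precision; the n-dimensional marginal covariance is
never formed (the observed-data likelihood uses the matrix-determinant
and inversion lemmas through the same factorization).

Row/column conventions are fixed so the design matrix is reproducible:
expression rows ordered probe-outer / condition-middle / replicate-inner,
methylation rows probe-outer / condition-inner; see `data.py`.

## Estimation

Hyperparameters `theta = (mu, Sigma, sigma2, delta2, omega2, tau2)` are
maximum-likelihood via EM over genes:

* **E-step** — per-gene posterior mean m_i and covariance V_i of beta_i.
  Genes with equal (J, H, K) share one posterior precision (the design
  and global error weights are identical), so the E-step factors each
  shape group once and handles its genes with a single matrix product.
* **M-step** — closed forms derived from the complete-data likelihood:
  mu is the mean of the gene-effect posterior means; Sigma the mean of
  `V_i[gene block] + (m_i - mu)(m_i - mu)'`; each probe-effect variance
  averages posterior second moments of its effects; each error variance
  averages expected squared residuals
  `||D - Delta m||^2 + tr(Delta V Delta')` over its platform's rows.
  These forms are unit-tested against an independent dense-loop oracle
  and guarded at run time by a hard error if the observed-data
  log likelihood ever decreases by more than 1e-6.

Starting values are method-of-moments: gene effects from probe-averaged
condition means, Sigma from their sample covariance, delta2 from
within-probe replicate variance. The methylation platform has no
replicates, so tau2 starts from the variance of within-gene-centered
paired condition differences (which estimates 2·tau2); sigma2/omega2
start from between-probe spread. Convergence: relative log-likelihood
change < 1e-8, default cap 500 iterations (typical fits converge in
~20). Sigma is symmetrized each M-step; eigenvalues below 1e-10 are
clipped up with a warning, and genuinely indefinite matrices (eigenvalue
< −1e-10) are an error. Variance updates are floored at 1e-10. Results
are invariant to gene input order (blocks are sorted by gene id before
grouping).

An expression-only marginal model (`ExpressionEBModel`, gene-effect
dimension 2) shares the entire EM core. When the cross block of Sigma is
forced to zero the joint likelihood factorizes, and the joint fit's
expression-side estimates coincide with the marginal fit — a separability
property the test suite checks to 1e-6.

## Classification and FDR

The change pair `(mu_i2 - mu_i1, eta_i2 - eta_i1)` has a bivariate normal
posterior (a linear contrast of the gene posterior). The plane is cut
into nine rectangles at thresholds ±C·sd per axis, where sd is the sample
standard deviation (denominator n−1) across genes of the posterior mean
change and C = 1.5 by default. Axis levels: DN/NG/UP for expression,
HO/NM/HR for methylation, relative to condition 1.

Rectangle probabilities use `scipy.stats.multivariate_normal.cdf` with
`lower_limit` (Genz's bivariate algorithm: deterministic, absolute error
far below the 1e-6 partition-of-unity tolerance enforced per gene).
Rectangles are half-open `[low, high)` so the regions partition the
plane; boundaries have probability zero. Assignment is by maximum
probability, with optional cutoffs 0.6 / 0.7 below which a gene stays
unassigned; argmax ties (probability ~0 events) resolve to the first
label in the fixed order DN/HO, DN/NM, DN/HR, NG/HO, …

For a category *s*, selecting genes with posterior probability
P_i^s ≥ κ gives the FDR estimate `sum(1 - P_i^s) / #selected` — the
standard posterior-probability FDR. An empty selection is reported as
undefined rather than zero. Raising κ never increases the selected count
or the numerator.

## Summaries

* Global correlations: Pearson across genes of posterior means —
  expression vs methylation level within each condition, and expression
  change vs methylation change. Note posterior means are shrunken; with
  strong coupling the correlation of posterior means can exceed the
  generative latent correlation slightly (observed ~0.03 at 3,000 genes).
* Gene-specific correlations: off-diagonal over sqrt of diagonal product
  of the relevant posterior 2×2 covariance (changes, and per-condition
  levels). These describe posterior dependence, the "local" view.
* Overlap tables: for two analyses sharing a gene universe, genes in a
  methylation stratum (e.g. HO) assigned in both are cross-tabulated by
  expression direction; cells sum to the intersection of qualifying sets.
* Score contrasts: for an external nonnegative per-gene score (e.g. a
  histone-mark level), the fold change of group means with a 95%
  percentile bootstrap CI (default 10,000 resamples, seeded, genes
  resampled within group). The CI method is a package choice; raw
  sequencing-read quantification is out of scope — any per-gene score
  table works.

## Synthetic data

`simulate.generate` samples the model exactly, emitting tables in the
package's TSV dialects plus ground truth (gene-effect 4-vectors, probe
effects, shift group). Defaults: 4 expression replicates, probe counts
uniform on {2, 3, 4} per platform, mu = (7, 7, 9.5, 9.5), within-platform
condition correlation 0.9 with gene variances 2.0 (expression) and 1.5
(methylation), cross-block entries −0.1·sqrt(diag product) (weak negative
coupling, the regime reported for promoter methylation versus
expression), sigma2 = 0.35, delta2 = 0.12, omega2 = 0.30, tau2 = 0.20.
Options: mark calls absent at a configured rate (to exercise the
present-call filter), emit `2**value` raw intensities (to exercise the
log2 step), and shift a fraction of genes' condition-2 means to plant
true categories. `truth_categories` labels each gene by the region
membership of its true change pair under a given grid — the reference
for FDR-calibration checks.

What the generator does *not* emulate: array spatial artifacts,
normalization residue, probe-specific variance heterogeneity,
heavy-tailed outliers, or negative within-gene probe correlation.
Passing tests therefore demonstrate correctness of the method under its
own assumptions, not robustness to real-array violations of them.

### Study sizes used in tests

Parameter-recovery checks run at 2,000 genes with a generating theta
whose covariance entries are all well above 0.1 in magnitude (cross
entries −0.5/−0.6): with I genes the sampling error of a cross entry is
about sqrt((Sigma_11·Sigma_33 + Sigma_13²)/I) ≈ 0.04 at I = 2,000, so
relative tolerances of 10–15% are only meaningful when entries are a few
times larger than that. FDR calibration pools 20 datasets of 500 genes;
EM-ascent checks use 20 datasets of 200 genes; the law-of-large-numbers
check on the generator uses 80,000 single-probe genes.

## Numerical choices

* Cholesky-based solves everywhere; explicit inverses only of the small
  per-shape posterior precision (needed as an output).
* PSD repair by eigenvalue clipping at 1e-10 with a warning; indefinite
  input is an error carrying the offending eigenvalue.
* TSV serialization uses `%.17g` and reading uses round-trip float
  parsing, so write→read is bit-exact.
* Probes mapping to multiple genes are dropped with a warning (the model
  assumes one gene per probe); missing values are rejected (the error
  covariance assumes complete blocks).
* Present-call filtering defaults to per-condition (≥ min_present "P"
  calls in *each* condition's replicate set, so both condition means stay
  estimable); a pooled variant over all 2K replicates is available via
  `per_condition=False` / `--pooled-calls`.

## Limitations

* No standard errors on the hyperparameter estimates (EM only).
* The Gaussian prior on gene effects is unimodal; planted-shift mixtures
  are mildly misspecified under it (posterior probabilities remain well
  calibrated in the regimes tested, but extreme mixtures may not be).
* Nine-region classification assumes thresholds symmetric about zero and
  shared across genes.
* One gene per probe; no support for missing replicates.
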