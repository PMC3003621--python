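# jointeb

Hierarchical empirical Bayes joint analysis of probe-level gene expression
and promoter DNA methylation between two conditions (e.g. a drug-resistant
cell line versus its parental, drug-sensitive line).

Microarray measurements of transcript abundance and of promoter CpG
methylation both arrive at the probe level, with several probes per gene
and substantial probe-to-probe variation. `jointeb` models the two
platforms together in a single hierarchical Gaussian model, so that each
gene gets a *joint posterior distribution* of its expression change and
its methylation change — a probabilistic answer to "is this gene
up-regulated and hypomethylated?", with probe variation, replicate noise
and the across-gene coupling of the two data types all accounted for.

## The model

For gene *i* with *J<sub>i</sub>* expression probes, *K* replicates and
*H<sub>i</sub>* methylation probes, on the log2 scale:

- expression: *G<sub>ijkl</sub>* = μ<sub>il</sub> + b<sub>ij</sub> + ε<sub>ijkl</sub>,
  with b<sub>ij</sub> ~ N(0, σ²), ε<sub>ijkl</sub> ~ N(0, δ²)
- methylation: *M<sub>ihl</sub>* = η<sub>il</sub> + a<sub>ih</sub> + d<sub>ihl</sub>,
  with a<sub>ih</sub> ~ N(0, ω²), d<sub>ihl</sub> ~ N(0, τ²)
- gene effects: (μ<sub>i1</sub>, μ<sub>i2</sub>, η<sub>i1</sub>, η<sub>i2</sub>)ᵀ ~ N(μ, Σ),

where *l* ∈ {1, 2} indexes condition and the 4×4 prior covariance Σ
carries a free 2×2 cross block coupling expression to methylation.
Stacking each gene's data as D = Δβ + ε gives a conjugate linear-Gaussian
block, so the posterior of β is normal with
cov = (ΔᵀΣ<sub>e</sub>⁻¹Δ + Σ<sub>p</sub>⁻¹)⁻¹ and
mean = cov·(ΔᵀΣ<sub>e</sub>⁻¹D + Σ<sub>p</sub>⁻¹μ*).

The hyperparameters θ = (μ, Σ, σ², δ², ω², τ²) are estimated by EM across
all genes (empirical Bayes). The posterior of the *changes*
(μ<sub>i2</sub> − μ<sub>i1</sub>, η<sub>i2</sub> − η<sub>i1</sub>) is a
bivariate normal; cutting the plane into nine rectangles at ±1.5·sd on
each axis yields per-gene probabilities of nine regulation categories
({down, no change, up} × {hypo, no change, hyper}), maximum-probability
assignment rules (plain, >0.6, >0.7), and a posterior-probability FDR
estimate: for genes selected at probability κ, FDR ≈ Σ(1 − P)/count.

## Worked example

```python
from jointeb import SimConfig, generate, build_gene_blocks, JointEBModel

expr, meth, truth = generate(SimConfig(n_genes=500, seed=42))
blocks, skip = build_gene_blocks(expr, meth)
res = JointEBModel(blocks).fit()
print(res.summary())
```

```
Joint empirical Bayes model (EM fit)
====================================================
genes: 500    iterations: 18    converged: True
log likelihood: -11854.0398

Gene-effect prior mean (mu):
  [6.9046 6.8822 9.4355 9.4179]
Gene-effect prior covariance (Sigma):
  [ 1.8263  1.6483 -0.1439 -0.0813]
  [ 1.6483  1.9145 -0.1179 -0.0853]
  [-0.1439 -0.1179  1.5519  1.4833]
  [-0.0813 -0.0853  1.4833  1.705 ]

probe-effect variance, expression  (sigma2): 0.33848
error variance, expression         (delta2): 0.12177
probe-effect variance, methylation (omega2): 0.31967
error variance, methylation        (tau2):   0.17586
```

The fitted μ and Σ recover the generator's setting (log2 expression near
7, methylation near 9.5, strongly correlated conditions, weak negative
cross-platform coupling), and the variance components split probe effects
from measurement noise. Classification and FDR then follow from the
per-gene posteriors:

```python
clf = res.classify()          # nine categories, rules max / >0.6 / >0.7
print(clf.table())
rep = next(r for r in clf.fdr_reports if r.category == "NG/NM")
print(f"FDR({rep.category}, kappa={rep.kappa}): "
      f"{rep.n_selected} genes selected, fdr_hat = {rep.fdr_hat:.4f}")
print(f"global correlation of changes: "
      f"{res.correlations().global_of_differences:.3f}")
```

```
          DN           NG        UP
HR     6/4/3     23/15/11     2/2/2
NM  37/29/24  375/344/319  22/13/12
HO     1/0/0     34/23/18     0/0/0

FDR(NG/NM, kappa=0.9): 207 genes selected, fdr_hat = 0.0441
global correlation of changes: -0.100
```

Each cell shows assigned-gene counts under the three rules
(max / >0.6 / >0.7); rows are methylation status (HR hypermethylated, NM
no change, HO hypomethylated), columns expression status. Most genes sit
in the no-change center, the counts nest as the cutoff rises, and the
global correlation of changes reflects the weak negative coupling the
data were generated with.

The same pipeline is available from the shell:

```bash
jointeb simulate --n-genes 500 --seed 42 --out data/
jointeb fit --expr data/expression.tsv --calls data/expression_calls.tsv \
            --meth data/methylation.tsv --out results/
```

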