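# diffconn

Differential-connectivity-gene (DCG) discovery from thresholded Pearson
co-expression networks.

Case/control transcriptomics is usually mined for *differential
expression*: genes whose mean level shifts with disease.  `diffconn`
targets a complementary signal, *differential connectivity*: genes whose
co-expression neighbourhood tightens under the disease condition, even
when their own expression change is modest.  The motivating setting is a
two-cohort microarray study of CD146⁺ blood cells in acute myocardial
infarction (AMI), where a handful of genes move from the periphery of
the healthy co-expression network into dense hub-centred clusters after
infarction.  The package is aimed at computational biologists who want
that analysis as a tested, scriptable library rather than a one-off
analysis.

## Method

Given a log2 expression matrix with `control`/`AMI` groups in a
`discovery` and a `validation` cohort:

1. **DEG screen.** Each gene passes through a cascade of two-sample
   tests: a distribution-shape test (two-sample Kolmogorov–Smirnov) at
   α₁; if the shape is not different, per-group normality (Shapiro–Wilk)
   at α₂ routes to Student's/Welch's *t* (after a Levene variance check
   at α₃) or to the Mann–Whitney rank-sum test, each at α₄.  Defaults
   are the deliberately stringent α₁ = 10⁻⁵, α₂ = 2·10⁻⁵,
   α₃ = α₄ = 10⁻⁵.
2. **Threshold networks.** For each group, genes *i*, *j* are connected
   when |r_ij| > x for Pearson correlation r and threshold x on the grid
   0.1–0.9.  Local connectivity is summarised by the clustering
   coefficient C_i = 2E_i/[k_i(k_i − 1)], where k_i is the degree and
   E_i the number of edges among neighbours of *i*.
3. **Network assessment.** The AMI-vs-control gap in the average C_i of
   the DEG set is profiled across thresholds (separable range, average
   separable width), clustered-gene counts are tracked per threshold,
   and degree distributions are checked against the scale-free power law
   p(k) ∝ k^(−γ), γ typically in [2, 3].
4. **DCG calling.** For each gene, the *band mean* of C_i over
   thresholds 0.4–0.8 is computed per group; the connectivity difference
   is band_mean(AMI) − band_mean(control).  Genes exceeding 0.1 in both
   cohorts are candidates; candidates that also exceed 0.1 in the pooled
   combination cohort are DCGs.
5. **Hub classification.** DCGs are placed in the plane (connectivity
   fold-change, log2 expression change); genes with fold-change > 2 and
   expression change > 0.4 (CC^high GeExp^high) are hub genes, and the
   DCGs adjacent to a hub at thresholds 0.5/0.7 form its cluster, with
   genes adjacent to several hubs flagged as bridges.

A synthetic-study generator plants hub blocks whose within-block
correlation rises from `rho_control` to `rho_ami` in the AMI group (plus
mean-shifted decoy genes and a weak background), so the whole pipeline
can be validated by parameter recovery without any external download.

## Worked example

```python
import diffconn as dc

spec = dc.default_recovery_spec(seed=1)          # 2 planted hub blocks
disc, valid, truth = dc.generate_study(spec)
report = dc.run_pipeline(dc.RunConfig(seed=1), disc, valid)

print(report["deg"])
print(report["n_candidates"], report["n_dcgs"])
```

prints

```
{'n_genes': 300, 'n_deg': 36, 'n_up': 36, 'n_down': 0}
16 16
```

36 of 300 genes pass the cascade screen (all upregulated, as planted:
the 20 shifted decoys plus the 17 block genes, minus one screen miss);
16 of them — all from the planted blocks, 16 of the 17 block genes —
show a clustering-coefficient difference above 0.1 in the discovery,
validation and combination cohorts and are called DCGs.  The discovery cohort's networks are
separable over thresholds 0.1–0.8 with an average separable width of
0.349, the designated block centres `G0021` and `G0030` are classified
CC^high GeExp^high (hub genes), and the declared shared gene `G0029` is
reported as a bridge between the two clusters.

The same run from the shell:

```sh
diffconn simulate --out study --seed 1
diffconn run --expr study/expr.tsv --pheno study/pheno.csv --out results
```

`results/` then holds the DEG table, per-cohort connectivity profiles,
the per-gene DCG report (`dcg_report.tsv`), hub clusters and a JSON
run report.

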