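# famomics

Variance-components analysis of familial resemblance in family-structured
omics (whole-blood gene expression and DNA methylation), with a seeded
family-omics simulator providing ground truth for every stage.

## The scientific problem

In a cohort of nuclear families, how much of the person-to-person
variation in each omic feature (an expression probe, a CpG site) is
explained by the family — and of that, how much is genetic versus shared
household environment?  For each feature *y* measured on related subjects
the package fits the classic variance-components model

    y ~ MVN(mu * 1,  Vg * A  +  Vc * H  +  Ve * I)

where `A = 2 * kinship` is the additive relationship matrix derived from
the pedigree, `H` the household (same-family) indicator, and the
nonnegative components are the polygenic (`Vg`), common-environment
(`Vc`) and unique-environment (`Ve`) variances.  From a fit it reports

* **maximal heritability** `h2_max = (Vg + Vc) / (Vg + Vc + Ve)`,
* **genetic heritability** `h2_g = Vg / (Vg + Vc + Ve)`,
* **common-environment share** `c2 = Vc / (Vg + Vc + Ve)`,

and tests the *familial effect* — the joint null `Vg = Vc = 0` — by
likelihood ratio, with Benjamini–Hochberg FDR across features.  Around
this core it implements the supporting stages such a study needs:
pedigree parsing and relative-pair summaries, detection filtering,
log/quantile normalization, covariate residualization (batch, position,
sex, age, age², interactions, cell proportions), reference-based blood
cell-type deconvolution (iteratively pruned nonnegative least squares),
a chunked cross-omic Pearson screen with Fisher-Z p-values and
Bonferroni control, bivariate fits estimating the genetic correlation
`rho_g` between an expression and a methylation feature, genomic window
overlap, and a generic hypergeometric over-representation test.

It is written for statistical geneticists and omics analysts who need a
transparent, fully tested ACE-style pipeline for small family designs —
and for anyone who wants to study the behaviour of such estimators on
simulated families, since no raw cohort data ship with the package.

## Worked example

The `analysis/` scripts run the whole chain on a simulated study-shaped
cohort: 48 subjects in 16 nuclear families (16 mothers, 6 fathers, 26
children), 500 features per omic of which 20% carry a planted familial
signal (Vg = 0.5, Vc = 0.3, Ve = 0.2), the rest pure noise.

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_relative_pair_correlations.py
python analysis/04_heritability_scan.py
python analysis/05_cross_omic_correlations.py
python analysis/06_window_overlap.py
```

Selected output (deterministic for the default seed):

```
expression: 192 of 500 features kept (38.4%)
mean |r| between relative pairs (across features):
             sibling  n=  13   0.241 +/- 0.155
    mother-offspring  n=  26   0.175 +/- 0.127
           unrelated  n=1078   0.022 +/- 0.008
expression: 192 features, 10 significant familial effects, 0 after FDR
           all: h2_max  13.0% (genetic   9.3%, common env   3.7%), 106 features at 0%
   significant: h2_max  66.9% (genetic  46.1%, common env  20.8%)
  planted fraction among significant: 1.00 (vs 0.17 overall)
screen: 10 x 12 features = 120 tests, Bonferroni threshold 0.000417
bivariate fits: 3/4 converged with a defined rho_g
```

Reading it: related pairs correlate an order of magnitude more strongly
than unrelated pairs (0.24 vs 0.022); the 38.4% detection-filter yield
follows from the simulated detection design; features flagged by the
familial LRT have far higher maximal heritability than the panel at
large (67% vs 13%) and are exactly the planted ones; and the unrelated
null mean |r| ≈ 0.022 matches the closed form sqrt(2/(pi·(P−1))) for
P = 1078 double-entered pairs.  The same chain is available as one call,
`famomics.run_pipeline(seed=7)`, whose reruns are byte-identical.

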