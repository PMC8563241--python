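# kradom

Quantitative-genetic analysis of a two-line terminal cross in poultry:
pedigree-based **additive + dominance animal models** (REML variance
components and BLUP), **midparent heterosis** from least-square line means,
and **marker-genotype association** with Tukey–Kramer mean comparisons.
A synthetic crossbreeding-data generator with known ground truth makes the
whole chain testable without external records.

The motivating setting is a slow-growing crossbred chicken: a sire line
(LK) mated to a dam line (SUT) produces the cross (KR). Body weight is
recorded at two-week intervals, parents are genotyped at two biallelic
candidate loci (growth hormone *GH*, alleles A1/A3; insulin-like growth
factor I *IGF-I*, alleles A/C), and the questions are (i) how much of the
cross's body-weight variance is additive vs. dominance, (ii) how large the
heterosis is, and (iii) whether marker genotypes track body weight or its
dominance deviations.

## The model

Body weight at one age is modelled with the animal model

```
y = Xβ + Za + Wd + ε
a ~ N(0, A σa²),   d ~ N(0, D σd²),   ε ~ N(0, I σε²)
```

where `β` holds the fixed effects (sex, hatch date), `A` is the numerator
relationship matrix from the pedigree (tabular method), `D` the dominance
relationship matrix (`d_ij = ¼(a(s_i,s_j)a(d_i,d_j) + a(s_i,d_j)a(d_i,s_j))`),
and `Z = W` assign records to animals. Variance components are estimated
by REML (EM steps with average-information acceleration), giving
heritability `h² = σa²/σp²` and the dominance ratio `σd²/σp²` with
`σp² = σa² + σd² + σε²`; BLUPs `â`, `d̂` solve Henderson's mixed-model
equations. Midparent heterosis at each age is

```
H% = 100 × [LSM_KR − (LSM_LK + LSM_SUT)/2] / [(LSM_LK + LSM_SUT)/2]
```

with least-square means adjusting for sex and hatch. Genotype effects on
any per-animal quantity are tested with a linear model (sex fixed), the
overall F-test, and Tukey–Kramer comparisons rendered as compact letters.

## Worked example

```python
from kradom import SimulationConfig, simulate_dataset, AdditiveDominanceModel
from kradom.heterosis import heterosis_table
from kradom.association import pearson_correlation

ds = simulate_dataset(SimulationConfig(seed=1))   # study-condition defaults
print(heterosis_table(ds.phenotypes, ages=[6]).round(2).to_string(index=False))

res = AdditiveDominanceModel.from_tables(
    ds.phenotypes, ds.pedigree, age=6, lines=("KR",)   # cross records only
).fit()
print(res.summary())
```

prints (output of this exact script):

```
 age_wk   n   mean  cv_percent    min     max  lsm_kr  lsm_lk  lsm_sut  heterosis_percent
      6 600 701.28       19.55 302.81 1054.72  701.28  570.55   568.85               23.1

Additive + dominance animal model (REML)
================================================
records: 600   animals: 1050
converged: True   iterations: 12
restricted log-likelihood: -3695.6104

component         estimate    std. error
----------------------------------------
sigma2_a        12297.9554     3671.4593
sigma2_d         5153.3646     2790.2228
sigma2_e            0.0000        0.0000
sigma2_p        17451.3201

h2 = 0.7047 (SE 0.1730)   sd2/sp2 = 0.2953
```

The simulated week-6 cross outweighs the parental-line midparent by 23.1%
(generating truth: 25%), and REML attributes most of the phenotypic
variance to additive effects with a substantial dominance share — the
generating components were (14250.04, 3314.70, 712.57) g². The residual
variance is pinned at its zero boundary here, a situation the real data
also produce at some ages. Correlating cross body weight with the
dominance BLUPs of the same fit:

```python
kr = ds.phenotypes[ds.phenotypes.line == "KR"]
pearson_correlation(kr.bw_g, res.d_hat.reindex(kr.animal).to_numpy())
# CorrelationResult(r=0.913, p=3e-235, n=600)
```

The same stages are scriptable from a shell:

```sh
kradom simulate --seed 1 --out-dir data/
kradom reml --pedigree data/ped.csv --pheno data/pheno.csv --age 6 --out fit6.csv
kradom heterosis --pheno data/pheno.csv --out heterosis.csv
kradom assoc --pheno data/pheno.csv --locus gh --age 6 --out assoc.csv
kradom run --config pipeline.yaml --out-dir results/   # everything at once
```

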