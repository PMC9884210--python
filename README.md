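# hcynet

Bayesian-network risk-factor analysis for hyperhomocysteinemia (HHcy,
serum homocysteine > 15 μmol/L) in categorical survey data — for
epidemiologists and biostatisticians who want the full modelling chain of
a published cross-sectional risk-factor study as reusable, tested code.

The pipeline mirrors the study design end to end:

1. **Coding** — guideline cut-offs turn raw measurements into the 21
   categorical analysis variables (demographics, lifestyle, lipids, FPG,
   GHb, blood pressure, BMI, urinary ACR/MCR, outcome).
2. **Univariate screen** — Pearson chi-square per variable vs outcome
   (Yates-corrected for 2×2).
3. **Multivariable selection** — stepwise logistic regression
   (likelihood-ratio entry α=0.05, removal α=0.10), odds ratios
   OR = exp(B) with 95% CI exp(B ± 1.96·SE).
4. **Structure learning** — the selected variables plus the outcome are
   the nodes of a Bayesian network G = (V, E) with joint
   P(X₁…Xₚ) = Π P(Xᵢ | pa(Xᵢ)), learned by maximising the decomposable
   BIC score `Σᵢ [Σⱼₖ nᵢⱼₖ ln(nᵢⱼₖ/nᵢⱼ)] − (ln n/2)(rᵢ−1)qᵢ` with **tabu
   search** (move memory over arcs, aspiration on the global best) and
   **hill climbing** for comparison.
5. **Parameters & reasoning** — maximum-likelihood CPTs; exact
   marginals/posteriors by variable elimination, including sequential
   risk queries such as P(HHcy | high SBP, age 71–91, abnormal MCR).
6. **Evaluation** — ROC/AUC (Mann–Whitney with DeLong 95% CI) per
   algorithm and target; structural Hamming distance and skeleton
   precision/recall/F1 against ground truth.

Because the study's raw records are not deposited, the package ships a
calibrated synthetic-population generator: a 10-node ground-truth network
(plus an extended 21-variable survey version) whose node marginals match
the published pooled frequencies exactly — including the HHcy prior
0.665 — and whose planted structure follows the published risk-factor
graph.  Every estimator is validated against brute-force oracles and
against this known ground truth.

## Worked example

```python
from hcynet import (PipelineConfig, run_pipeline, posterior,
                    chi_square_test, table1_tables)
from hcynet.synthetic import hhcy_network

# chi-square screen on the published count tables
print(round(chi_square_test(table1_tables()["Exercise"]).p, 3))  # 0.436
print(round(chi_square_test(table1_tables()["BMI"]).p, 3))       # 0.022

# sequential Bayesian reasoning on the ground-truth network
bn = hhcy_network()
for ev in ({}, {"SBP": "High"}, {"SBP": "High", "Age": "71-91"},
           {"SBP": "High", "Age": "71-91", "MCR": "Abnormal"}):
    print(round(posterior(bn, "Hcy", ev).p("HHcy"), 3))
# 0.665, 0.727, 0.797, 0.851  — risk rises as evidence accumulates

# the full pipeline on a simulated survey of 12,285 subjects
report = run_pipeline(PipelineConfig(simulate="survey", n=12285, seed=0))
print(report.summary())
```

The pipeline summary printed by the last call:

```
subjects: 12285
screen: 15 of 20 variables significant (alpha=0.05)
stepwise: selected Sex, Age, MCR, Diet, SBP, FPG
tabu: 7 nodes, 7 directed edges; P(Hcy) prior = 0.668
hc: 7 nodes, 7 directed edges; P(Hcy) prior = 0.668
AUC[tabu, Hcy] = 0.650 (95% CI 0.640-0.661)
AUC[hc, Hcy] = 0.650 (95% CI 0.640-0.661)
tabu vs hc: SHD 2, skeleton F1 1.000
```

Chi-square screening keeps 15 of 20 variables at this sample size (the
weakly chained lipid variables lose power at n ≈ 12k), stepwise keeps the
six direct risk factors, and both search algorithms learn the same
7-node skeleton whose outcome AUC (0.650) sits in the range the study
reports for its networks.

## Command line

```bash
hcynet simulate --n 12285 --seed 0 --out pop.csv --truth truth.bif
hcynet screen --data pop.csv --outcome Hcy --alpha 0.05
hcynet select --data pop.csv --alpha-in 0.05 --alpha-out 0.10
hcynet learn-structure --data pop.csv --algorithm tabu --score bic --out dag.json
hcynet fit-params --data pop.csv --dag dag.json --out net.bif
hcynet infer --network net.bif --target Hcy --evidence SBP=High,Age=71-91
hcynet pipeline --config config.yaml --out run/
```

## Analysis scripts

`analysis/01…05` re-run the study's narrative in order — published-table
worked examples, population simulation, screen + stepwise, structure
learning and recovery, reasoning and ROC — writing small tables under
`results/`.

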