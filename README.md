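# thalscore

Three-SNP genetic risk score for clinical severity of β⁰-thalassemia/HbE.

Patients compound-heterozygous for a β⁰-thalassemia allele and hemoglobin E
span a wide clinical spectrum, from transfusion-independent (mild) to
transfusion-dependent (severe) disease. Three SNPs at the classical
HbF-modifier loci — rs766432 (*BCL11A*), rs9399137 (*HBS1L–MYB* intergenic)
and rs72872548 (*HBE1*) — shift the odds of severe disease. `thalscore` is
for genetics labs and biostatisticians who want to (re)run this analysis on
published group-level genotype frequencies or on their own individual-level
cohorts (CSV or VCF).

## The method

**Risk-genotype association.** For a genotype *g* of one SNP, carriers are
contrasted against the two other genotypes pooled between two severity
groups in a 2×2 table (a, b; c, d). The effect is the odds ratio
OR = ad/bc (first-named group in the numerator; Haldane–Anscombe +0.5 on
every cell iff some cell is zero), with the Woolf interval

    exp( ln OR ± z_{1−α/2} · √(1/a + 1/b + 1/c + 1/d) )

and a two-sided Fisher exact p-value. Published percentages are inverted to
integer counts by nearest rounding with largest-remainder repair, so the
counts always sum to the group sizes (180 mild / 181 moderate / 307 severe
in the packaged discovery-cohort table).

**Risk score.** Each SNP's genotypes score 0/1/2 from low to high risk
(rs766432 CC/AC/AA, rs9399137 CC/TC/TT, rs72872548 AA/AC/CC); the total
S ∈ [0, 6] is binned by three interpretation models:

| total S | model 1 | model 2 | model 3 |
|---------|---------|---------|---------|
| 0–3 | mild | mild | mild |
| 4 | moderate | moderate | moderate |
| 5 | moderate **or** severe | severe | moderate |
| 6 | severe | severe | severe |

Model 1's two-class bin at S = 5 is kept as a genuine set-valued
prediction; evaluation resolves it by an explicit policy (`pessimistic` →
severe, `optimistic` → moderate, `exclude`). Metrics: sensitivity and
specificity treat severe as the positive class (one-vs-rest), accuracy is
3-class agreement.

**Simulation.** Because no individual-level data are published, a seeded
generator draws cohorts from the per-group multinomial genotype marginals
(independent SNPs by default; an optional Gaussian copula adds LD-like
dependence), and an exact enumeration over the 27 genotype combinations per
group gives closed-form expected metrics under independence.

## Worked example

```python
>>> import thalscore as ts
>>> res = ts.SeverityAssociation.reference().fit()
>>> row = [r for r in res.results
...        if (r.snp_id, r.genotype) == ("rs766432", "AA")
...        and r.comparison_label == "mild_vs_severe"][0]
>>> round(row.odds_ratio, 2), round(row.ci_low, 2), round(row.ci_high, 2)
(0.39, 0.26, 0.59)
```

AA at rs766432 is about 2.5× *less* frequent (OR 0.39, 95% CI 0.26–0.59)
among mild than severe patients — i.e. it is the risk genotype for severe
disease. Scoring a simulated cohort with the published marginals:

```python
>>> cfg = ts.SimulationConfig(frequency_table=ts.load_reference_frequencies(), seed=7)
>>> fit = ts.RiskScoreAnalysis.from_simulation(cfg).fit(policy="pessimistic")
>>> print(fit.metrics.to_string(index=False))
 model          cohort      policy   n  sensitivity_pct  specificity_pct  accuracy_pct
model1 simulated-seed7 pessimistic 668             73.0             57.1          48.8
model2 simulated-seed7 pessimistic 668             73.0             57.1          48.8
model3 simulated-seed7 pessimistic 668             26.7             92.5          38.3
```

Under the pessimistic policy model 1 coincides with model 2 (their only
difference is where total 5 goes), and model 3 trades sensitivity for
specificity. These simulated metrics assume independent SNPs within each
severity group — see `docs/methods.md` for why that matters.

The same pipeline from the shell:

```
thalscore reproduce --seed 7 --out-dir reproduction
thalscore simulate --freq-table src/thalscore/data/cohort1_genotype_frequencies.csv \
    --seed 7 --out cohort.csv
thalscore score --cohort cohort.csv --out scores.csv
thalscore evaluate --cohort cohort.csv --policy pessimistic --out eval.csv
```

`reproduce` writes `association_comparison.csv` (the 27-row scan with
2-d.p. match flags against the packaged published values) plus a Markdown
report, and exits non-zero if any OR/CI cell fails to match.

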