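# Methods

## Data model

The analysis targets β⁰-thalassemia/HbE, where severity (mild / moderate /
severe, assigned by a clinical instrument upstream of this package) is
modified by three biallelic HbF-modifier SNPs: rs766432 (*BCL11A*, chr2:
60 492 835), rs9399137 (*HBS1L–MYB*, chr6: 135 097 880) and rs72872548
(*HBE1*, chr11: 5 267 909; GRCh38 coordinates). Genotypes are canonicalised
to the declared allele order (het printed first-allele-first, e.g. `AC`,
`TC`), which makes published genotype strings usable verbatim.

Group-level input is a per-severity genotype-percentage table with group
sizes; the packaged discovery-cohort table has n = 180/181/307. Percentages
were evidently computed from integer counts at 2 decimal places, so counts
are reconstructed by nearest-integer rounding of `pct/100·n`, with a
largest-remainder repair (one unit at a time to the cell with the greatest
rounding residual, ties broken by genotype order) guaranteeing that counts
sum to n. For every cell of the packaged table the rounded value is within
0.05 of an integer, so the reconstruction is exact there; for arbitrary
percentages the repaired count can deviate from `pct/100·n` by up to one
unit (not half a unit: with three cells the repaired cell's residual can
reach 2/3).

Patients with any missing predictive genotype have an undefined total score
and are excluded from scoring and evaluation, with the exclusions counted
and reported. No imputation, phasing, multi-allelic handling or liftover is
attempted.

## Association

Each genotype is contrasted against the pooled complement (genotype vs.
rest) between two severity groups, ordered comparisons mild–moderate,
mild–severe, moderate–severe, with the first-named group's odds in the
numerator. OR = ad/bc; the Haldane–Anscombe +0.5 correction is applied to
OR and CI only when a raw cell is zero (no packaged-table row needs it).
The 95% CI is Woolf's log-normal interval. No multiple-testing correction
is applied; 27 tests are reported as raw values.

Two numerical facts about the published reference table matter for
comparisons:

* The printed CI bounds are **truncated** to 2 d.p., not rounded (computed
  0.587 prints as 0.58, 75.436 as 75.43, 1.3397 as 1.33), while ORs are
  conventionally rounded. "Agreement at 2 d.p." is therefore implemented as
  round-equality for ORs and one-printed-unit (|Δ| < 0.01) agreement for CI
  bounds. Under this reading all 27 OR cells and all 54 CI bounds
  reproduce.
* The published p-values were produced by an unnamed SPSS procedure. The
  shipped test is the two-sided Fisher exact test (sum of hypergeometric
  probabilities ≤ the observed table's). It matches many printed rows to
  the printed precision but not all, and no standard alternative (Pearson
  χ², Yates-corrected χ²) matches the remainder either. P-values are
  therefore reported side by side (a `p_ratio` column) and never flagged as
  match/mismatch. The Fisher implementation is validated instead against an
  exact-rational enumeration oracle, exhaustively for all 2×2 tables with
  every margin ≤ 30.

## Scoring and evaluation

Per-SNP scores (0/1/2, low to high risk) and model bins are config-driven
YAML; the packaged default encodes the three-SNP system above. Model
validation enforces full coverage of totals 0..2k (k SNPs), contiguous
prediction sets, and monotonicity of both the minimal and maximal predicted
class in the total.

Model 1's bin at total 5 is the set {moderate, severe}; it is never
silently resolved. Evaluation policies: `pessimistic` (→ severe; the
default, favouring detection of transfusion-dependent disease),
`optimistic` (→ moderate), `exclude` (dropped, with the exclusion counted).
Because total 5 is the only difference between the models, model 1 under
`pessimistic` predicts identically to model 2, and under `optimistic`
identically to model 3 — a useful internal consistency check, asserted in
the tests.

Sensitivity = P(predicted severe | true severe) and specificity pools
mild+moderate as not-severe; this one-vs-rest reading with severe positive
is an assumption (the source table's definitions are unstated) and is the
one consistent with the clinical framing of detecting severe disease.
Accuracy is 3-class agreement of the resolved prediction; a `lenient`
variant (correct when the truth lies anywhere in the unresolved prediction
set) is available behind a flag. A metric whose denominator class is absent
from the cohort is NaN, never 0.

## Simulation

`simulate_cohort` draws each group's patients from the configured
multinomial genotype marginals with a single `numpy` generator seeded from
the config (no global state); the same seed yields a byte-identical
cohort. Default group sizes are the table's (180/181/307). Missingness is
uniform per (patient, SNP).

Across SNPs the default is conditional independence given the severity
group, because only marginals are published; this is a modelling
assumption, not a claim about the real cohorts. The copula mode draws a
latent Gaussian vector with common pairwise correlation ρ and maps each
coordinate through the marginal inverse CDF with genotypes ordered by risk
score, preserving marginals while coupling the per-SNP scores; ρ = 0
recovers the independent distribution.

`expected_metrics` computes exact sensitivity/specificity/accuracy under
independence by enumerating the 27 genotype combinations per group
(product-multinomial probabilities, group-size weights); under the
`exclude` policy metrics condition on the non-excluded probability mass. It
is the oracle against which Monte-Carlo runs are checked (agreement within
3 binomial standard errors at n ≈ 10⁵, simulation seed 7, group sizes
scaled ×150 to 27 000/27 150/46 050 — sizes chosen to keep the check sharp
at modest cost).

**What the simulation does and does not show.** Passing tests demonstrate
that the pipeline's arithmetic is correct and internally consistent; they
do not validate the published three-cohort metric table, which depends on
the joint genotype distribution of the real patients. Under independence
the expected cohort-1-sized metrics (model 1, pessimistic: sensitivity
72.2%, specificity 54.8%, accuracy 48.7%) differ materially from the
published values (60.0 / 76.7 / 71.2): real risk genotypes are evidently
positively dependent given severity (all three loci act on the same HbF
axis), which concentrates totals at the extremes and raises specificity and
accuracy. The discrepancy is reported as evidence about the independence
assumption, not treated as an error to be fitted away; the copula mode
exists to explore exactly this sensitivity.

## Numerical choices and degenerate inputs

* Frequency-table validation: per SNP per group percentages must sum to
  100 within ±0.05 (the worst drift a 2-d.p. printed table can accumulate).
* Fisher ties: tables with probability within a 1 + 10⁻⁷ relative factor of
  the observed one count as ties, the standard convention for floating
  implementations; the test oracle uses exact integer arithmetic with the
  same tie rule.
* Woolf CI at α → 1 collapses onto the point OR; α outside (0, 1) is
  rejected.
* Zero-count genotypes contribute nothing to allele frequencies; an
  all-zero count table raises rather than returning NaNs.
* Empty scorable set is a logged warning, not an error, so batch runs over
  many cohorts do not abort.

## Known limitations

* The independence default understates the real models' accuracy (above);
  conclusions about model ranking on simulated data carry that caveat.
* Sensitivity/specificity definitions for the 3-class problem, and the
  handling of model-1 total-5 patients in the published metric table, are
  assumptions surfaced as explicit policies rather than recovered facts.
* VCF support is a minimal on-ramp: GT field only, biallelic records
  matched by rsID, samples labelled via a sidecar CSV.
* Different populations have different allele frequencies and LD structure;
  the packaged scoring system is specific to the Southeast-Asian
  β⁰-thalassemia/HbE setting it was derived in.
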