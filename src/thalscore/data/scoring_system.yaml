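# Default three-SNP severity scoring system for beta0-thalassemia/HbE.
# Per-genotype scores run 0/1/2 from low to high risk of severe disease;
# the total over the three SNPs (0-6) is binned into predicted severity
# classes by three alternative interpretation models.  Model 1's moderate
# and severe bins intentionally overlap at total 5.
snps:
  - snp_id: rs766432
    gene: BCL11A
    chromosome: "2"
    position: 60492835
    alleles: [A, C]
    scores: {CC: 0, AC: 1, AA: 2}
  - snp_id: rs9399137
    gene: HBS1L-MYB
    chromosome: "6"
    position: 135097880
    alleles: [T, C]
    scores: {CC: 0, TC: 1, TT: 2}
  - snp_id: rs72872548
    gene: HBE1
    chromosome: "11"
    position: 5267909
    alleles: [A, C]
    scores: {AA: 0, AC: 1, CC: 2}
models:
  model1: {mild: [0, 3], moderate: [4, 5], severe: [5, 6]}
  model2: {mild: [0, 3], moderate: [4, 4], severe: [5, 6]}
  model3: {mild: [0, 3], moderate: [4, 5], severe: [6, 6]}
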