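# Published per-genotype odds ratios (genotype vs. the two others pooled),
# Woolf 95% confidence intervals and p-values for the Thai discovery cohort,
# as printed in the original severity analysis (2 decimal places; CI bounds
# appear truncated, not rounded, in the source). The p-values were produced
# by an unnamed test in SPSS and serve as verification references only.
snp_id,genotype,comparison,or,ci_low,ci_high,p
rs766432,AA,mild_vs_moderate,0.76,0.49,1.17,0.23
rs766432,AA,mild_vs_severe,0.39,0.26,0.58,4.98e-6
rs766432,AA,moderate_vs_severe,0.51,0.34,0.77,1.45e-3
rs766432,AC,mild_vs_moderate,1.36,0.87,2.10,0.18
rs766432,AC,mild_vs_severe,2.44,1.61,3.69,2.09e-5
rs766432,AC,moderate_vs_severe,1.80,1.17,2.74,7.95e-3
rs766432,CC,mild_vs_moderate,0.88,0.31,2.46,1.00
rs766432,CC,mild_vs_severe,2.03,0.67,6.13,0.24
rs766432,CC,moderate_vs_severe,2.32,0.79,6.79,0.15
rs9399137,TT,mild_vs_moderate,0.44,0.28,0.69,3.63e-4
rs9399137,TT,mild_vs_severe,0.35,0.23,0.51,2.16e-7
rs9399137,TT,moderate_vs_severe,0.78,0.50,1.20,0.31
rs9399137,TC,mild_vs_moderate,2.21,1.39,3.48,6.73e-4
rs9399137,TC,mild_vs_severe,2.63,1.75,3.96,3.35e-6
rs9399137,TC,moderate_vs_severe,1.19,0.76,1.86,0.49
rs9399137,CC,mild_vs_moderate,1.70,0.39,7.20,0.50
rs9399137,CC,mild_vs_severe,8.74,1.01,75.43,2.78e-2
rs9399137,CC,moderate_vs_severe,5.16,0.53,49.95,0.14
rs72872548,AA,mild_vs_moderate,7.84,2.29,26.77,9.36e-5
rs72872548,AA,mild_vs_severe,7.98,2.95,21.55,3.51e-6
rs72872548,AA,moderate_vs_severe,1.02,0.24,4.31,1.00
rs72872548,AC,mild_vs_moderate,1.06,0.64,1.74,0.89
rs72872548,AC,mild_vs_severe,2.05,1.33,3.12,1.09e-3
rs72872548,AC,moderate_vs_severe,1.93,1.27,2.93,2.33e-3
rs72872548,CC,mild_vs_moderate,0.42,0.22,0.76,5.40e-3
rs72872548,CC,mild_vs_severe,0.21,0.12,0.36,2.25e-9
rs72872548,CC,moderate_vs_severe,0.50,0.32,0.77,1.98e-3
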