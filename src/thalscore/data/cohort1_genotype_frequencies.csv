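# Published genotype frequencies (%) of the three HbF-modifier SNPs among
# beta0-thalassemia/HbE patients of the Thai discovery cohort, stratified by
# clinical severity (180 mild, 181 moderate, 307 severe; 668 total).
# The __n__ row carries the per-group sample sizes.
snp_id,genotype,mild,moderate,severe
__n__,,180,181,307
rs766432,CC,3.89,4.42,1.95
rs766432,AC,37.22,30.39,19.54
rs766432,AA,58.89,65.19,78.50
rs9399137,CC,2.78,1.66,0.33
rs9399137,TC,40.00,23.20,20.20
rs9399137,TT,57.22,75.14,79.48
rs72872548,AA,11.67,1.66,1.63
rs72872548,AC,78.33,77.35,63.84
rs72872548,CC,10.00,20.99,34.53
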