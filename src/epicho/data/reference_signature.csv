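cell_line,mRNA_HC_LC_pct,H2A,H3.3,H2A.Z,H3K9ac,H3K9me3,H3K4me3,H3K27me3,FAIRE,Nuc853,Nuc1008,methylation_pct
PT1-1,1.00,19.50,22.00,5.26,2.17,3.90,8.04,17.20,46.90,60.00,86.67,6.25
PT1-7,53.50,6.67,79.94,135.97,218.15,66.96,5.41,32.23,2.60,60.67,66.67,0.00
PT1-30,22.36,13.31,16.73,11.13,61.99,97.82,17.90,51.18,6.00,73.33,80.00,2.08
PT1-55,104.00,2.93,66.45,7.29,189.00,577.78,16.40,47.40,207.50,87.50,62.50,0.71
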