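method,prefix,n_tested,n_converted,n_mapped,n_diversity_polymorphic
cDNA-STA,GMI_ES01-17,2270,991,757,878
cDNA-CTA,GMI_ES_CC,336,144,98,133
DArT-CTA,GMI_DS_CC,300,121,87,108
DArT-Sanger,GMI_DS_A/oPt,66,48,36,43
genomic-tetraploid,GMI_grs,100,7,7,7
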