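genome,chromosome,length_cm,n_markers,est_snp,dart_snp,ccdd_snp,ssr,sts,resistance_genes,duplicate_loci
A,8A,87.1,35,28,8,0,1,0,0,2
A,11A,41.9,24,20,2,0,2,1,0,0
A,13A,134.6,64,50,8,0,6,0,0,1
A,15A,85.7,31,26,3,0,2,0,0,4
A,16A,85.6,85,75,5,0,5,0,0,1
A,17A-7C,53.1,11,10,1,0,0,0,0,3
A,19A,115.5,78,58,13,0,7,1,0,1
C,1C,74.8,89,80,8,0,1,0,0,0
C,2C,76.2,64,53,9,0,2,0,0,0
C,3C,93.5,55,45,7,2,1,1,0,0
C,4C,97.0,26,19,6,1,0,0,0,0
C,5C,126.0,94,85,6,1,2,0,0,3
C,6C,95.4,52,41,10,0,1,0,0,1
C,7C-17A,83.9,43,33,7,2,1,0,0,1
D,9D,105.4,100,84,11,0,2,0,3,4
D,10Da,4.8,8,8,0,0,0,0,0,0
D,10Db,23.2,4,2,0,0,0,0,2,0
D,12D,133.1,63,50,13,0,0,0,0,1
D,14D,132.5,48,41,4,0,3,0,0,1
D,18D,47.2,44,40,1,0,0,0,0,1
D,20D,76.7,28,23,4,1,0,0,0,0
D,21D,65.6,11,8,3,0,0,0,0,0
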