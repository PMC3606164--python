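genome,length_cm,n_markers
A,603.5,328
C,646.8,417
D,588.5,306
all,1838.8,1053
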