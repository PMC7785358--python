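locus,allele,freq
FGA,18,0.1
FGA,19,0.1
FGA,20,0.1
FGA,21,0.1
FGA,22,0.1
FGA,23,0.1
FGA,24,0.1
FGA,25,0.1
FGA,26,0.1
FGA,27,0.1
SE33,14,0.0625
SE33,15,0.0625
SE33,16,0.0625
SE33,17,0.0625
SE33,18,0.0625
SE33,19,0.0625
SE33,20,0.0625
SE33,21,0.0625
SE33,22,0.0625
SE33,23,0.0625
SE33,24,0.0625
SE33,25,0.0625
SE33,26,0.0625
SE33,27,0.0625
SE33,28,0.0625
SE33,29,0.0625
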