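institution,cases,total_snakes,n_affected_species,prevalence_pct
1,32,162,20,19.8
2,10,72,4,13.9
3,16,77,9,20.8
4,19,250,14,7.6
5,31,651,26,4.8
6,25,1049,16,2.4
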