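label,count,sum,mean,variance
direct,196,2157.122,11.006,42.696
one_synergy,196,2025.910,10.336,19.789
two_synergy,196,1895.985,9.673,18.365
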