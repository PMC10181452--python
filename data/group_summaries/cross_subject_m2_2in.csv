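label,count,sum,mean,variance
direct,196,2792.539,14.248,41.462
one_synergy,196,2646.628,13.503,24.561
two_synergy,196,2440.454,12.451,23.557
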