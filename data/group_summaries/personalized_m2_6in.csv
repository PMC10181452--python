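label,count,sum,mean,variance
direct,14,86.756,6.197,4.672
one_synergy,14,107.930,7.709,7.335
two_synergy,14,108.972,7.784,7.748
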