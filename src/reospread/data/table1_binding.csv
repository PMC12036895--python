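virus,replicate,percent_bound
T3wt,1,80.64
T3wt,2,58.25
T3wt,3,45.99
SV5,1,24.25
SV5,2,34.10
SV5,3,14.19
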