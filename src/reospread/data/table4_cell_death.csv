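virus,time_h,percent_dead
T3wt,15,1.470
T3wt,18,40.15
T3wt,24,34.38
T3wt,24,46.79
T3wt,24,28.99
T3wt,30,58.64
T3wt,30,78.08
T3wt,36,62.35
T3wt,36,80.63
SV5,15,1.34
SV5,18,39.05
SV5,24,25.68
SV5,24,44.69
SV5,24,23.39
SV5,30,45.34
SV5,30,76.28
SV5,36,52.15
SV5,36,77.83
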