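interval,"<0.5,1>","<0,0.5)","<0.2,0.5)","<0,0.2)","<0.1,0.2)","<0,0.1)"
"<0.5,1>",32.41,43.08,33.39,45.68,37.62,47.95
"<0,0.5)",45.40,10.36,19.85,10.41,12.95,10.83
"<0.2,0.5)",35.47,23.42,20.71,25.70,22.31,26.67
"<0,0.2)",44.97,10.49,21.05,10.45,13.70,10.77
"<0.1,0.2)",37.01,15.28,17.56,16.51,13.07,17.83
"<0,0.1)",47.78,11.32,23.86,11.14,15.31,11.03
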