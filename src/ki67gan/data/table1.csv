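interval,"<0.5,1>","<0,0.5)","<0.2,0.5)","<0,0.2)","<0.1,0.2)","<0,0.1)"
"<0.5,1>",15.16,19.10,16.45,19.85,17.18,20.52
"<0,0.5)",19.72,5.67,9.80,5.52,7.13,5.59
"<0.2,0.5)",20.50,8.17,9.90,8.42,9.45,8.57
"<0,0.2)",22.12,5.45,10.26,5.59,7.24,5.65
"<0.1,0.2)",19.53,6.52,8.76,6.59,6.61,7.01
"<0,0.1)",20.77,5.86,10.75,5.67,7.72,5.64
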