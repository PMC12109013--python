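interval,"<0.5,1>","<0,0.5)","<0.2,0.5)","<0,0.2)","<0.1,0.2)","<0,0.1)"
"<0.5,1>",0.00,40.95,31.47,44.38,32.75,47.80
"<0,0.5)",40.95,0.00,12.82,0.30,6.19,0.87
"<0.2,0.5)",31.47,12.82,0.00,16.81,9.43,19.56
"<0,0.2)",44.38,0.30,16.81,0.00,7.72,0.24
"<0.1,0.2)",32.75,6.19,9.43,7.72,0.00,10.58
"<0,0.1)",47.80,0.87,19.56,0.24,10.58,0.00
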