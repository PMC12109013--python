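interval,"<0.5,1>","<0,0.5)","<0.2,0.5)","<0,0.2)","<0.1,0.2)","<0,0.1)"
"<0.5,1>",0.42,33.87,13.11,38.12,29.10,41.70
"<0,0.5)",33.87,0.45,9.99,0.70,3.27,1.05
"<0.2,0.5)",13.11,9.99,0.44,12.92,5.72,15.35
"<0,0.2)",38.12,0.70,12.92,0.44,4.41,0.61
"<0.1,0.2)",29.10,3.27,5.72,4.41,0.42,6.00
"<0,0.1)",41.70,1.05,15.35,0.61,6.00,0.44
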