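group,sequence,rater,verdict
1,1,1,partially real and unreal
1,1,2,certainly real
1,2,1,partially real and unreal
1,2,2,rather real
1,3,1,rather real
1,3,2,rather real
1,4,1,rather unreal
1,4,2,rather unreal
1,5,1,partially real and unreal
1,5,2,partially real and unreal
1,6,1,rather real
1,6,2,partially real and unreal
1,7,1,rather real
1,7,2,rather real
1,8,1,partially real and unreal
1,8,2,certainly unreal
1,9,1,rather real
1,9,2,rather unreal
1,10,1,partially real and unreal
1,10,2,rather unreal
1,11,1,rather real
1,11,2,rather real
1,12,1,partially real and unreal
1,12,2,certainly unreal
1,13,1,rather unreal
1,13,2,rather unreal
1,14,1,rather real
1,14,2,rather unreal
1,15,1,rather real
1,15,2,certainly real
1,16,1,rather real
1,16,2,certainly real
1,17,1,rather unreal
1,17,2,rather real
1,18,1,partially real and unreal
1,18,2,partially real and unreal
1,19,1,rather real
1,19,2,partially real and unreal
1,20,1,partially real and unreal
1,20,2,rather real
2,1,1,rather unreal
2,1,2,rather unreal
2,2,1,rather unreal
2,2,2,rather unreal
2,3,1,rather real
2,3,2,certainly real
2,4,1,rather unreal
2,4,2,certainly unreal
2,5,1,rather unreal
2,5,2,rather unreal
2,6,1,partially real and unreal
2,6,2,certainly real
2,7,1,rather unreal
2,7,2,partially real and unreal
2,8,1,rather real
2,8,2,rather unreal
2,9,1,rather real
2,9,2,rather real
2,10,1,certainly real
2,10,2,certainly unreal
2,11,1,rather real
2,11,2,certainly unreal
2,12,1,partially real and unreal
2,12,2,rather unreal
2,13,1,rather unreal
2,13,2,certainly real
2,14,1,rather real
2,14,2,rather unreal
2,15,1,partially real and unreal
2,15,2,rather real
2,16,1,rather real
2,16,2,certainly real
2,17,1,certainly unreal
2,17,2,partially real and unreal
2,18,1,rather real
2,18,2,certainly real
2,19,1,certainly real
2,19,2,partially real and unreal
2,20,1,rather real
2,20,2,rather unreal
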