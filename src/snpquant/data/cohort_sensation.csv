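zone,timepoint,value,sd
applicator,baseline,58,4
applicator,day3,5,6
applicator,month1,23,15
applicator,month4,39,17
applicator,month7,56,4
central,baseline,58,4
central,day3,8,6
central,month1,23,17
central,month4,41,19
central,month7,57,5
distal,baseline,58,4
distal,day3,23,12
distal,month1,37,17
distal,month4,50,18
distal,month7,54,17
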