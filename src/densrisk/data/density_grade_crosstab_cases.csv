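birads,vpd1,vpd2,vpd3,vpd4
1,59,16,1,0
2,50,101,35,3
3,5,36,93,29
4,0,0,7,39
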