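birads,vpd1,vpd2,vpd3,vpd4
1,388,98,6,0
2,217,445,208,8
3,4,116,434,124
4,0,2,32,161
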