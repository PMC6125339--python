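index,value,uncertainty
1,-17.81,0.01
2,-20.06,0.03
3,-25.1,0.05
4,-30.1,0.06
5,-34.98,0.07
6,-39.9,0.08
7,-44.82,0.11
8,-49.78,0.16
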