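name,min,max
USS_H,-14.815,-9.5475
BETAS_H,-10.444,-6.383
ZS_H,0.85244,1.5053
GSS_H,10.953,15.822
FN11_H,0.14962,0.23173
FN21_H,1.2161,1.4849
FN31_H,0.83875,1.0458
ALPB_H,3.9629,4.8467
XFAC_H,2.3077,2.7852
USS_C,-52.553,-45.61
UPP_C,-43.679,-37.301
BETAS_C,-15.285,-11.804
BETAP_C,-9.2246,-6.7715
ZS_C,1.5914,2.2229
ZP_C,1.501,2.0466
GSS_C,10.314,13.662
GSP_C,9.7585,13.092
GPP_C,9.3945,12.464
GP2_C,8.6452,11.014
HSP_C,0.66956,0.77601
FN11_C,0.045528,0.055036
FN21_C,4.3632,5.1283
FN31_C,1.4298,1.7154
ALPB_HC,0.76974,1.1501
XFAC_HC,0.15181,0.21488
ALPC_C,2.3296,3.0615
XFAC_C,0.71959,0.96953
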