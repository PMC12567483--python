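compound_id,logd74,pka_basic
LASSBio-2123,1.86,6.81
LASSBio-2124,2.38,6.59
LASSBio-2125,2.90,6.52
LASSBio-2129,2.32,6.46
LASSBio-2130,2.41,6.63
sitagliptin,0.45,7.70
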