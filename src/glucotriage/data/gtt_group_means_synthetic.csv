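group,time_min,glycemia_mg_dl
hyperglycemic,0,100.0
hyperglycemic,15,380.0
hyperglycemic,30,340.0
hyperglycemic,60,300.0
hyperglycemic,120,225.0
hyperglycemic,180,150.0
sitagliptin,0,100.0
sitagliptin,15,178.6
sitagliptin,30,200.6
sitagliptin,60,237.0
sitagliptin,120,89.65
sitagliptin,180,100.0
LASSBio-2123,0,100.0
LASSBio-2123,15,311.6
LASSBio-2123,30,149.6
LASSBio-2123,60,220.0
LASSBio-2123,120,180.0
LASSBio-2123,180,130.0
LASSBio-2124,0,102.0
LASSBio-2124,15,375.0
LASSBio-2124,30,338.0
LASSBio-2124,60,296.0
LASSBio-2124,120,222.0
LASSBio-2124,180,152.0
LASSBio-2125,0,98.0
LASSBio-2125,15,383.0
LASSBio-2125,30,344.0
LASSBio-2125,60,303.0
LASSBio-2125,120,228.0
LASSBio-2125,180,149.0
LASSBio-2129,0,100.0
LASSBio-2129,15,220.4
LASSBio-2129,30,241.4
LASSBio-2129,60,270.0
LASSBio-2129,120,148.95
LASSBio-2129,180,120.0
LASSBio-2130,0,100.0
LASSBio-2130,15,288.8
LASSBio-2130,30,322.0
LASSBio-2130,60,291.0
LASSBio-2130,120,220.0
LASSBio-2130,180,148.0
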