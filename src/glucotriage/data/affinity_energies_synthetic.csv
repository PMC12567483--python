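compound_id,target,ea_kcal_mol
LIT,aldose_reductase,-8.598
1JD,glucokinase,-7.625
LASSBio-2123,aldose_reductase,-8.9
LASSBio-2123,glucokinase,-8.3
LASSBio-2124,aldose_reductase,-9.2
LASSBio-2124,glucokinase,-8.6
LASSBio-2125,aldose_reductase,-9.8
LASSBio-2125,glucokinase,-9.1
LASSBio-2129,aldose_reductase,-11.085
LASSBio-2129,glucokinase,-10.352
LASSBio-2130,aldose_reductase,-9.0
LASSBio-2130,glucokinase,-8.4
sitagliptin,aldose_reductase,-9.5
sitagliptin,glucokinase,-8.9
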