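# Five beta-amino-N-acylhydrazone DPP-4 inhibitor candidates plus the
# sitagliptin comparator. Structures reconstructed from the published
# IUPAC name of LASSBio-2129 with benzylidene-ring substituents varied
# per the series scheme (di-OMe, F, di-Cl, F at the alternate position).
N[C@@H](CC(=O)N/N=C/c1ccc(OC)c(OC)c1)Cc1cc(F)c(F)cc1F	LASSBio-2123
N[C@@H](CC(=O)N/N=C/c1ccc(F)cc1)Cc1cc(F)c(F)cc1F	LASSBio-2124
N[C@@H](CC(=O)N/N=C/c1ccc(Cl)c(Cl)c1)Cc1cc(F)c(F)cc1F	LASSBio-2125
N[C@@H](CC(=O)N/N=C/c1ccc(F)c(F)c1)Cc1cc(F)c(F)cc1F	LASSBio-2129
N[C@@H](CC(=O)N/N=C/c1cccc(F)c1)Cc1cc(F)c(F)cc1F	LASSBio-2130
N[C@@H](CC(=O)N1CCn2c(nnc2C(F)(F)F)C1)Cc1cc(F)c(F)cc1F	sitagliptin
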