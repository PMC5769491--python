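# S-phase marker genes (mouse symbols) for the proliferation index:
# DNA-replication licensing and synthesis machinery.  A compact subset of
# the standard S-phase program; replace with an assay-specific list if one
# is available.
Mcm2
Mcm3
Mcm4
Mcm5
Mcm6
Mcm7
Pcna
Rrm1
Rrm2
Cdc6
Cdc45
Ccne1
Ccne2
Gins2
Fen1
Prim1
Pola1
Tyms
Dtl
Uhrf1
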