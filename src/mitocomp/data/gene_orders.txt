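# Signed circular mitochondrial gene arrangements, one per line:
# name <TAB> comma-separated symbols, "-" prefix = light (minus) strand.
# Each line is one full traversal of the circle anchored at cox1(+).
#
# ancestral_pancrustacean: the plesiomorphic pancrustacean/decapod ground
#   pattern (the Drosophila-like arrangement) used as the comparison baseline.
# palaemon_pattern: the arrangement shared by most Palaemon species, incl.
#   P. macrodactylus (OQ512152) and P. tenuidactylus (OP650931); differs from
#   the ancestral pattern by the transposed trnT/trnP pair.
# brevicarpalis_pattern: Ancylocaris brevicarpalis (NC_061664); 16S and trnV
#   transposed relative to the ancestral pattern.
# picta_pattern: Hymenocera picta (NC_039631); the block
#   nad1-trnL1-16S-trnV-12S-trnI-trnQ relocated from downstream of trnS2 to
#   downstream of nad4l.  The published description lists the moved block
#   without the CR; the CR is kept at the vacated position downstream of
#   trnS2 here (comparisons exclude the CR by default).
# australis_pattern: Anchistus australis (NC_046034); trnL2 absent, trnL1
#   transposed with 16S, and trnW transposed with the trnC-trnY block.
ancestral_pancrustacean	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cytb,trnS2,-nad1,-trnL1,-16S,-trnV,-12S,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
palaemon_pattern	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,-trnP,trnT,nad6,cytb,trnS2,-nad1,-trnL1,-16S,-trnV,-12S,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
brevicarpalis_pattern	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cytb,trnS2,-nad1,-trnL1,-trnV,-16S,-12S,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
picta_pattern	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,-nad1,-trnL1,-16S,-trnV,-12S,trnI,-trnQ,trnT,-trnP,nad6,cytb,trnS2,CR,trnM,nad2,trnW,-trnC,-trnY
australis_pattern	cox1,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cytb,trnS2,-nad1,-16S,-trnL1,-trnV,-12S,CR,trnI,-trnQ,trnM,nad2,-trnC,-trnY,trnW
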