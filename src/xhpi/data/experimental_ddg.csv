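# xhpi-schema: 1.0
# Published double-mutant-cycle interaction energies (kcal/mol) for the
# XH...pi pairs of protein GB3 and the stabilized staphylococcal nuclease
# variant D+PHS, measured by GdnHCl denaturation.  "background" names the
# extra mutation(s) carried by all four cycle variants; kind CH_pi = methyl
# donor, NH_pi = side-chain amide donor.
protein,background,pair,kind,ddg_kcal_mol,sigma_kcal_mol
GB3,WT,L5-F30,CH_pi,-0.81,0.05
GB3,WT,L5-Y33,CH_pi,-0.65,0.06
GB3,WT,I7-Y33,CH_pi,-0.13,0.06
GB3,WT,T16-Y33,CH_pi,-0.70,0.05
GB3,WT,T16-F33,CH_pi,-0.68,0.05
GB3,WT,T18-F30,CH_pi,-0.08,0.05
GB3,L5V,T16-Y33,CH_pi,-0.29,0.06
GB3,L5V,T18-F30,CH_pi,0.09,0.06
GB3,I7V,T16-Y33,CH_pi,-0.25,0.06
GB3,T16A,L5-Y33,CH_pi,-0.26,0.06
GB3,T16A,I7-Y33,CH_pi,0.31,0.05
GB3,T18A,L5-F30,CH_pi,-0.65,0.06
GB3,N37A,L5-Y33,CH_pi,-0.34,0.06
GB3,N37A,I7-Y33,CH_pi,0.11,0.06
GB3,N37A,T16-Y33,CH_pi,-0.85,0.06
GB3,Y33F-N37A,T16-F33,CH_pi,-0.29,0.06
D+PHS,WT,L25-F34,CH_pi,-0.41,0.05
D+PHS,WT,V74-F34,CH_pi,-0.53,0.07
D+PHS,WT,I92-F34,CH_pi,-0.46,0.06
D+PHS,L25V,V74-F34,CH_pi,-0.83,0.05
D+PHS,L25V,I92-F34,CH_pi,-0.84,0.06
D+PHS,V74A,L25-F34,CH_pi,-0.72,0.04
D+PHS,V74A,I92-F34,CH_pi,-0.51,0.05
D+PHS,I92V,L25-F34,CH_pi,-0.81,0.08
D+PHS,I92V,V74-F34,CH_pi,-0.59,0.07
GB3,WT,N37-Y33,NH_pi,-0.68,0.05
GB3,L5V,N37-Y33,NH_pi,-0.37,0.07
GB3,I7V,N37-Y33,NH_pi,-0.45,0.06
GB3,T16A,N37-Y33,NH_pi,-0.86,0.06
GB3,Y33F,N37-F33,NH_pi,-0.83,0.06
GB3,Y33F-T16A,N37-F33,NH_pi,-0.15,0.06
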