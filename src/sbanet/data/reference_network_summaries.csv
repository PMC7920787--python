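regime,habitat,n_species,active_nodes,n_edges,density_pct,sips_intra,sips_inter,bips_intra,bips_inter,hub_species
R1,BG,8,12,78,2.7,5,73,38,40,ANAL;ANFA;CINI
R1,DW,6,11,66,2.3,12,54,14,52,CYCO
R1,GL,10,23,253,10.5,20,233,77,176,ANAL
R1,SW,13,33,496,21.9,36,460,127,369,CYCO
R1,MF,14,40,780,32.3,46,734,200,580,ARAL;ARCI;CINI
R2,BG,3,6,15,0.6,4,11,3,12,ANCY
R2,DW,6,17,136,5.6,22,114,28,108,CYCO
R2,GL,6,17,136,5.6,21,115,28,108,ANFA;ARAL
R2,SW,11,27,378,14.5,30,348,95,283,CYCO
R2,MF,11,33,528,21.9,38,490,135,393,ANFA;PLLE
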