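species_id,scientific_name,guild
CINI,Ciconia nigra,G1
ARAL,Ardea alba,G1
ARCI,Ardea cinerea,G1
CIBO,Ciconia boyciana,G1
ANCY,Anser cygnoides,G1
GRLE,Grus leucogeranus,G2
GRMO,Grus monacha,G2
CYCO,Cygnus columbianus,G2
GRGR,Grus grus,G3
ANAL,Anser albifrons,G3
ANFA,Anser fabalis,G3
PLLE,Platalea leucorodia,G4
LASP,Larus spp.,G5
PEON,Pelecanus onocrotalus,G5
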