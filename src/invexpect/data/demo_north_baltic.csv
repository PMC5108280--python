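name,kingdom,phylum,class,native_regions,north_sea,baltic_sea
Dreissena polymorpha,Animalia,Mollusca,Bivalvia,ponto_caspian,1,1
Marenzelleria viridis,Animalia,Annelida,Polychaeta,northwest_atlantic,1,1
Crassostrea gigas,Animalia,Mollusca,Bivalvia,northwest_pacific,1,0
Mnemiopsis leidyi,Animalia,Ctenophora,Tentaculata,northwest_atlantic;southwest_atlantic,1,1
Eriocheir sinensis,Animalia,Arthropoda,Malacostraca,northwest_pacific;yangtze,1,1
Cercopagis pengoi,Animalia,Arthropoda,Branchiopoda,ponto_caspian,0,1
Elodea canadensis,Plantae,Tracheophyta,Liliopsida,north_america,1,1
Bonnemaisonia hamifera,Plantae,Rhodophyta,Florideophyceae,northwest_pacific,1,0
Acartia tonsa,Animalia,Arthropoda,Maxillopoda,unknown,1,1
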