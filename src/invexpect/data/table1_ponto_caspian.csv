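name,kingdom,phylum,class,native_regions,north_sea,baltic_sea,great_lakes,st_lawrence_river
Paranais frici,Animalia,Annelida,Clitellata,ponto_caspian,0,1,0,0
Potamothrix bedoti,Animalia,Annelida,Clitellata,ponto_caspian,0,1,1,0
Potamothrix heuscheri,Animalia,Annelida,Clitellata,ponto_caspian,0,1,0,0
Potamothrix moldaviensis,Animalia,Annelida,Clitellata,ponto_caspian,0,0,1,0
Potamothrix vejdovskyi,Animalia,Annelida,Clitellata,ponto_caspian,0,1,1,0
Hypania invalida,Animalia,Annelida,Polychaeta,ponto_caspian,1,1,0,0
Cercopagis pengoi,Animalia,Arthropoda,Branchiopoda,ponto_caspian,0,1,1,0
Cornigerius maeoticus,Animalia,Arthropoda,Branchiopoda,ponto_caspian,0,1,0,0
Evadne anonyx,Animalia,Arthropoda,Branchiopoda,ponto_caspian,0,1,0,0
Chelicorophium (=Corophium) curvispinum,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,1,0,0
Chelicorophium robustum,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,0,0,0
Dikerogammarus haemobaphes,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,1,0,0
Dikerogammarus villosus,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,1,0,0
Echinogammarus ischnus,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,1,1
Echinogammarus warpachowskyi,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Hemimysis anomala,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,1,1,0
Jaera istri,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,0,0,0
Limnomysis benedeni,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Obesogammarus crassus,Animalia,Arthropoda,Malacostraca,ponto_caspian,1,1,0,0
Paramysis (=Mesomysis) intermedia,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Paramysis (=Serrapalpisis) lacustris,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Pontogammarus robustoides,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Pseudocuma (=Stenocuma) graciloides,Animalia,Arthropoda,Malacostraca,ponto_caspian,0,1,0,0
Eurytemora affinis,Animalia,Arthropoda,Maxillopoda,ponto_caspian,0,0,1,1
Nitocra hibernica,Animalia,Arthropoda,Maxillopoda,ponto_caspian,0,0,1,0
Nitocra incerta,Animalia,Arthropoda,Maxillopoda,ponto_caspian,0,0,1,0
Schizopera borutzkyi,Animalia,Arthropoda,Maxillopoda,ponto_caspian,0,0,1,0
Victorella pavida,Animalia,Bryozoa,Gymnolaemata,ponto_caspian,1,1,0,0
Acipenser gueldenstaedtii,Animalia,Chordata,Actinopterygii,ponto_caspian,1,1,0,0
Acipenser oxyrinchus,Animalia,Chordata,Actinopterygii,ponto_caspian,0,1,0,0
Acipenser ruthenus,Animalia,Chordata,Actinopterygii,ponto_caspian,1,1,0,0
Acipenser stellatus,Animalia,Chordata,Actinopterygii,ponto_caspian,0,1,0,0
Cyprinus carpio,Animalia,Chordata,Actinopterygii,ponto_caspian,0,1,1,1
Huso huso,Animalia,Chordata,Actinopterygii,ponto_caspian,0,1,0,0
Neogobius fluviatilis,Animalia,Chordata,Actinopterygii,ponto_caspian,1,1,0,0
Neogobius kessleri,Animalia,Chordata,Actinopterygii,ponto_caspian,1,0,0,0
Neogobius melanostomus,Animalia,Chordata,Actinopterygii,ponto_caspian,1,1,1,1
Proterorhinus marmoratus,Animalia,Chordata,Actinopterygii,ponto_caspian,0,1,1,0
Cordylophora caspia,Animalia,Cnidaria,Hydrozoa,ponto_caspian,1,1,1,0
Maeotias marginata,Animalia,Cnidaria,Hydrozoa,ponto_caspian,0,1,0,0
Moerisia (=Ostroumovia) inkermanica,Animalia,Cnidaria,Hydrozoa,ponto_caspian,1,0,0,0
Pachycordyle navis,Animalia,Cnidaria,Hydrozoa,ponto_caspian,1,1,0,0
Dreissena rostriformis bugensis,Animalia,Mollusca,Bivalvia,ponto_caspian,1,1,1,1
Dreissena polymorpha,Animalia,Mollusca,Bivalvia,ponto_caspian,1,1,1,1
Lithoglyphus naticoides,Animalia,Mollusca,Gastropoda,ponto_caspian,0,1,0,0
Theodoxus pallasi,Animalia,Mollusca,Gastropoda,ponto_caspian,0,1,0,0
Viviparus acerosus,Animalia,Mollusca,Gastropoda,ponto_caspian,1,0,0,0
Sphaeromyxa sevastopoli,Animalia,Myxozoa,Myxosporea,ponto_caspian,0,0,1,0
Ichthyocotylurus pileatus,Animalia,Platyhelminthes,Trematoda,ponto_caspian,0,0,1,0
Neascus brevicaudatus,Animalia,Platyhelminthes,Trematoda,ponto_caspian,0,0,1,0
Psammonobiotus communis,Chromista,Cercozoa,,ponto_caspian,0,0,1,0
Psammonobiotus dziwnowi,Chromista,Cercozoa,Gromiidea,ponto_caspian,0,0,1,0
Psammonobiotus linearis,Chromista,Cercozoa,Gromiidea,ponto_caspian,0,0,1,0
Acineta nitocrae,Chromista,Ciliophora,Phyllopharyngea,ponto_caspian,0,0,1,0
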