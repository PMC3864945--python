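taxon	category	common_name
Actinopterygii	food	Bony fish
Amphipoda	food	Amphipod shrimps
Anthomedusae	food	Cnidarian jelly
Asellota	food	Isopod shrimps
Bangiaceae	food	Red alga
Calanoida	food	Calanoid copepods
Canalipalpata	food	Fan-headed worms
Caryophyllales	food	Pearlworts
Collembola	food	Springtails
Cyclopoida	food	Cyclopoid copepods
Cephalopoda	food	Squid, Octopus
Ctenophora	food	Comb jellies
Euphausiidae	food	Krill
Harpacticoida	food	Copepods
Mysida	food	Opossum shrimps
Ostracoda	food	Seed shrimps
Palmariaceae	food	Red alga
Phaeophyceae	food	Brown alga
Pleocyemata	food	Shrimps
Pteropoda	food	Sea butterflies
Porifera	food	Sponges
Salpidae	food	Salps
Scyphozoa	food	Jellyfish
Siphonophora	food	Bluebottles
Siphonostomatoida	food	Siphonostomatoid copepods
Aves	contaminant	Birds
Agaricomycotina	contaminant	Fungus
Anthozoa	contaminant	Sessile cnidarians
Bacillariophyta	contaminant	Diatoms
Coleoptera	contaminant	Beetles
Diplopoda	contaminant	Millipedes
Diptera	contaminant	Flies
Glomeromycetes	contaminant	Fungus
Neoptera	contaminant	Bees
Pezizomycotina	contaminant	Mold
Primates	contaminant	Apes, monkeys, humans
Pucciniomycotina	contaminant	Fungus
Taphrinomycotina	contaminant	Fungus
Tardigrada	contaminant	Water bears
Turbellaria	contaminant	Flatworms
Acanthocephala	parasite	Thorny-headed worms
Cestoda	parasite	Tapeworms
Monogenea	parasite	Ectoparasitic platyhelminths
Mucoromycotina	parasite	Fungal gut parasite
Nematoda	parasite	Roundworm
Oribatida	parasite	Mites
Trematoda	parasite	Flukes
Trichomonadidae	parasite	Unicellular parasites
Apicomplexa	unicell
Chlamydomonadaceae	unicell
Chromulinaceae	unicell
Chrysophyceae	unicell
Ciliophora	unicell
Dinophyceae	unicell
Euamoebida	unicell
Oomycetes	unicell
Rhizaria	unicell
Saccharomycotina	unicell
Silicofilosea	unicell
Vannellidae	unicell
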