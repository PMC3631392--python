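species,records,iucn_status,note
Eutriorchis astur,10,Endangered,
Mesitornis variegata,5,Vulnerable,
Mesitornis variegata,1,Vulnerable,eastern_disjunct
Mesitornis unicolor,14,Vulnerable,
Monias benschi,1,Endangered,
Tyto soumagnei,7,Endangered,
Brachypteracias leptosomus,25,Vulnerable,
Brachypteracias squamigera,18,Vulnerable,
Uratelornis chimaera,2,Vulnerable,
Neodrepanis hypoxantha,13,Vulnerable,
Calicalicus rufocarpalis,5,Vulnerable,
Oriolia bernieri,11,Vulnerable,
Xenopirostris damii,2,Endangered,
Euryceros prevostii,10,Vulnerable,
Newtonia fanovanae,7,Vulnerable,
Monticola erythronotus,1,Endangered,
Bernieria apperti,3,Vulnerable,
Bernieria tenebrosus,3,Vulnerable,
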