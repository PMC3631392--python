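species,area_2000,area_2050,maxprob_2000,maxprob_2050,alt_min_2000,alt_max_2000,alt_min_2050,alt_max_2050
Oriolia bernieri,99841,0,0.894,0.203,0,2744,1456,2405
Euryceros prevostii,136251,41,0.904,0.337,0,2744,999,2568
Mesitornis unicolor,148966,436,0.929,0.337,0,2744,1551,2506
Neodrepanis hypoxantha,73147,1270,0.951,0.475,12,2745,1145,2744
Eutriorchis astur,112149,6867,0.909,0.592,0,2744,609,2744
Tyto soumagnei,112377,31813,0.92,0.761,0,2744,242,2744
Brachypteracias leptosomus,102898,38622,0.993,0.498,0,2744,3,2744
Newtonia fanovanae,148260,70430,0.887,0.848,0,2744,1,2744
Brachypteracias squamigera,79047,43734,0.993,0.83,0,2744,0,2405
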