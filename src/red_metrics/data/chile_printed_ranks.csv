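metric,rank,species
red,1,Lactoris fernandeziana
red,2,Juania australis
red,3,Tecophilaea cyanocrocus
red,4,Placea amoena
red,5,Leontochir ovallei
red,6,Placea lutea
red,7,Megalachne masafuerana
red,8,Megalachne berteroana
red,9,Cuminia eriantha
red,10,Metharme lanata
red,11,Sanctambrosia manicata
red,12,Gomortega keule
red,13,Nothomyrcia fernandeziana
red,14,Nesocaryum stylosum
red,15,Leucocoryne foetida
red,16,Rimacactus laui
red,17,Valdivia gayana
red,18,Ochagavia elegans
red,19,Pintoa chilensis
red,20,Yunquea tenzii
iucn50,1,Lactoris fernandeziana
iucn50,2,Gomortega keule
iucn50,3,Leontochir ovallei
iucn50,4,Juania australis
iucn50,5,Placea amoena
iucn50,6,Tecophilaea cyanocrocus
iucn50,7,Megalachne masafuerana
iucn50,8,Metharme lanata
iucn50,8,Pintoa chilensis
iucn50,9,Pitavia punctata
iucn50,10,Cuminia eriantha
iucn50,11,Sanctambrosia manicata
iucn50,12,Placea lutea
iucn50,13,Conanthera urceolata
iucn50,14,Legrandia concinna
iucn50,15,Avellanita bustillosii
iucn50,16,Gethyum atropurpureum
iucn50,17,Nesocaryum stylosum
iucn50,18,Miersia cornuta
iucn50,19,Microphyes robusta
iucn50,20,Selkirkia berteroi
iucn100,1,Lactoris fernandeziana
iucn100,2,Gomortega keule
iucn100,3,Leontochir ovallei
iucn100,4,Megalachne masafuerana
iucn100,5,Juania australis
iucn100,6,Placea amoena
iucn100,7,Cuminia eriantha
iucn100,8,Tecophilaea cyanocrocus
iucn100,9,Sanctambrosia manicata
iucn100,10,Metharme lanata
iucn100,10,Pintoa chilensis
iucn100,11,Pitavia punctata
iucn100,12,Nesocaryum stylosum
iucn100,13,Placea lutea
iucn100,14,Conanthera urceolata
iucn100,15,Legrandia concinna
iucn100,16,Avellanita bustillosii
iucn100,17,Gethyum atropurpureum
iucn100,18,Miersia cornuta
iucn100,19,Microphyes robusta
iucn100,20,Neoporteria sociabilis
iucn500,1,Lactoris fernandeziana
iucn500,2,Gomortega keule
iucn500,3,Leontochir ovallei
iucn500,4,Juania australis
iucn500,5,Placea amoena
iucn500,6,Tecophilaea cyanocrocus
iucn500,7,Metharme lanata
iucn500,7,Pintoa chilensis
iucn500,8,Pitavia punctata
iucn500,9,Megalachne masafuerana
iucn500,10,Placea lutea
iucn500,11,Conanthera urceolata
iucn500,12,Jubaea chilensis
iucn500,13,Legrandia concinna
iucn500,14,Avellanita bustillosii
iucn500,15,Cuminia eriantha
iucn500,16,Gethyum atropurpureum
iucn500,17,Sanctambrosia manicata
iucn500,18,Miersia cornuta
iucn500,19,Nesocaryum stylosum
iucn500,20,Microphyes robusta
isaac,1,Lactoris fernandeziana
isaac,2,Gomortega keule
isaac,3,Leontochir ovallei
isaac,4,Juania australis
isaac,5,Megalachne masafuerana
isaac,6,Placea amoena
isaac,7,Tecophilaea cyanocrocus
isaac,8,Cuminia eriantha
isaac,9,Metharme lanata
isaac,9,Pintoa chilensis
isaac,10,Sanctambrosia manicata
isaac,11,Pitavia punctata
isaac,12,Jubaea chilensis
isaac,13,Placea lutea
isaac,14,Nesocaryum stylosum
isaac,15,Conanthera urceolata
isaac,16,Legrandia concinna
isaac,17,Avellanita bustillosii
isaac,18,Gethyum atropurpureum
isaac,19,Miersia cornuta
isaac,20,Megalachne berteroana
ed_all,1,Lactoris fernandeziana
ed_all,2,Gomortega keule
ed_all,2,Peumus boldus
ed_all,3,Epipetrum bilobum
ed_all,4,Epipetrum humile
ed_all,5,Lapageria rosea
ed_all,5,Leontochir ovallei
ed_all,6,Lardizabala biternata
ed_all,7,Epipetrum polyanthes
ed_all,8,Juania australis
ed_all,8,Jubaea chilensis
ed_all,9,Desmaria mutabilis
ed_all,9,Notanthera heterophylla
ed_all,10,Placea amoena
ed_all,11,Tecophilaea cyanocrocus
ed_all,11,Tecophilaea violiflora
ed_all,12,Conanthera bifolia
ed_all,13,Zephyra compacta
ed_all,13,Zephyra elegans
ed_all,14,Metharme lanata
ed_all,14,Pintoa chilensis
ed_all,15,Scyphanthus elegans
ed_all,16,Hollermayera valdiviana
ed_all,17,Bakerolimon plumosum
ed_all,18,Trevoa quinquenervia
ed_all,19,Bridgesia incisifolia
ed_all,19,Pitavia punctata
ed_all,20,Huidobria chilensis
ed_all,20,Huidobria fruticosa
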