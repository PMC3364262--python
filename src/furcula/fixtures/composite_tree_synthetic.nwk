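(Tyrannosaurus:90,(Falcarius:3,Neimongosaurus:50):40,(Oviraptor:83,(Anchiornis:33,(Bambiraptor:25,Velociraptor:25):55,(Archaeopteryx:5,Confuciusornis:30,Eoconfuciusornis:30,Sapeornis:30,Zhongjianornis:30,((Cathayornis:9,Concornis:9,Eoalulavis:9,Iberomesornis:9,Longipteryx:9,Noguerornis:9,Pengornis:9,Protopteryx:9,Rapaxavis:9,Vescornis:9):9,((Hongshanornis:6,Longicrusavis:6,Ornithuromorpha_gen_et_sp_indet:6,Gansus:6):2,(((Anas_platyrhynchos:55,Cygnus_olor:55,Oxyura_australis:55):30,Chauna_torquata:85):25,Hirundapus_caudacutus:110,(Eurostopodus_mystacalis:85,Podargus_strigoides:85):25,(Cerorhinca_monocerata:85,Esacus_giganteus:85,Vanellus_miles:85,Chionis_minor:85,Stiltia_isabella:85,Larus_novaehollandiae:85,Recurvirostra_novaehollandiae:85,Rostratula_benghalensis:85,Rynchops_niger:85,(Limosa_lapponica:55,Numenius_arquata:55):30,Stercorarius_skua:85):25,((Leptoptilos_dubius:55,Mycteria_americana:55):30,Threskiornis_spinicollis:85,Ajaja_ajaja:85):25,Phaps_elegans:110,(Megaceryle_torquata:85,Dacelo_novaeguineae:85,Momotus_momota:85):25,Cuculus_canorus:110,((Accipiter_fasciatus:55,Circus_cyaneus:55,Geranospiza_caerulescens:55,Pandion_haliaetus:55):30,((Falco_peregrinus:28,Falco_rusticolus:28):27,Herpetotheres_cachinnans:55):30,Sagittarius_serpentarius:85):25,(Macrocephalon_maleo:85,Leipoa_ocellata:85,(Guttera_plumifera:55,Numida_meleagris:55):30,(Argusianus_agrus:55,Coturnix_pectoralis:55):30):25,(Ardeotis_australis:85,Fulica_atra:85):25,(Coracina_novaehollandiae:85,Corcorax_melanoramphos:85,(Corvus_coronoides:28,Corvus_mellori:28,Corvus_ossifragus:28):57,Tityra_semifasciata:85,Gymnorhina_tibicen:85,Grallina_cyanoleuca:85,Menura_novaehollandiae:85,Colluricincla_harmonica:85,Oriolus_sagittatus:85,Ptilonorhynchus_violaceus:85,Sturnus_vulgaris:85,Tyrannus_melancholicus:85):25,((Anhinga_novaehollandiae:28,Anhinga_rufa:28):57,(Ardea_pacifica:55,Cochlearius_cochlearius:55):30,Phalacrocorax_carbo:85,(Morus_bassanus:28,Morus_serrator:28):57):25,Phaethon_rubricauda:110,Phoenicopterus_ruber:110,Colaptes_auratus_cafer:110,(Aechmophorus_occidentalis:55,Podiceps_cristatus:55):55,(Thalassarche_chrysostoma:85,(Diomedea_epomophora:28,Diomedea_immutabilis:28):57,Pagodroma_nivea:85,Pelecanoides_urinatrix:85,Pterodroma_macroptera:85):25,(Cacatua_sanguinea:85,Anodorhynchus_hyacinthinus:85):25,(Aptenodytes_patagonicus:55,(Eudyptes_chryosolophus:28,Eudyptes_chrysocome:28):27,Spheniscus_humboldti:55):55,((Ninox_novaeseelandiae:55,Pulsatrix_perspicellata:55):30,Tyto_alba:85):25,(Crypturellus_cinnamomeus:55,Tinamus_major:55):55):20):10):12):3):3):7);
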