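no,taxon,order,family,common_name,specimen_id,flight_mode
1,Accipiter fasciatus,Falconiformes,Accipitridae,Brown Goshawk,MV W6645,FG
2,Aechmophorus occidentalis,Podicipediformes,Podicipedidae,Western Grebe,YPM 104291,CF
3,Ajaja ajaja,Ciconiiformes,Threskiornithidae,Roseate Spoonbill,YPM 102558,FG
4,Anas platyrhynchos,Anseriformes,Anatidae,Mallard,AMNH 5847,CF
5,Anhinga novaehollandiae,Pelecaniformes,Anhingidae,Australasian Darter,MV B8674,SS
6,Anhinga rufa,Pelecaniformes,Anhingidae,African Darter,YPM 103994,S
7,Anodorhynchus hyacinthinus,Psittaciformes,Psittacidae,Hyacinth Macaw,MCZ 346739,CF
8,Aptenodytes patagonicus,Sphenisciformes,Spheniscidae,King Penguin,MCZ 347208,SUB
9,Ardea pacifica,Pelecaniformes,Ardeidae,White-necked Heron,MV B6820,CF
10,Ardeotis australis,Gruiformes,Otididae,Australian Bustard,MV B8566,PF
11,Argusianus agrus,Galliformes,Phasianidae,Great Argus,AMNH 4969,CF
12,Cacatua sanguinea,Psittaciformes,Cacatuidae,Little Corella,MV W5474,CF
13,Cerorhinca monocerata,Charadriiformes,Alcidae,Rhinoceros Auklet,MV B12388,CF
14,Chauna torquata,Anseriformes,Anhimidae,Southern Screamer,AMNH 3616,CF
15,Chionis minor,Charadriiformes,Chionididae,Black-faced Sheathbill,MV W3457,CF
16,Circus cyaneus,Falconiformes,Accipitridae,Hen Harrier,MCZ 342125,S
17,Cochlearius cochlearius,Pelecaniformes,Ardeidae,Boat-billed Heron,AMNH 3494,CF
18,Colaptes auratus cafer,Piciformes,Picidae,Red-shafted Flicker,MV B12384,CF
19,Colluricincla harmonica,Passeriformes,Muscicapidae,Grey Shrikethrush,MV B12031,IB
20,Coracina novaehollandiae,Passeriformes,Campephagidae,Black-faced Cuckoo-shrike,MV B10770,IB
21,Corcorax melanoramphos,Passeriformes,Corcoracidae,White-winged Chough,MV B11506,IB
22,Corvus coronoides,Passeriformes,Corvidae,Australian Raven,MV R7711,FG
23,Corvus mellori,Passeriformes,Corvidae,Little Raven,MV B10351,FG
24,Corvus ossifragus,Passeriformes,Corvidae,Fish Crow,AMNH 1050,FG
25,Coturnix pectoralis,Galliformes,Phasianidae,Stubble Quail,MV B9799,PF
26,Crypturellus cinnamomeus,Tinamiformes,Tinamidae,Thicket Tinamou,MV B4785,PF
27,Cuculus canorus,Cuculiformes,Cuculidae,Common Cuckoo,YPM 105038,CF
28,Cygnus olor,Anseriformes,Anatidae,Mute Swan,MCZ 347051,CF
29,Dacelo novaeguineae,Coraciiformes,Halcyonidae,Laughing Kookaburra,MV B12052,CF
30,Diomedea epomophora,Procellariiformes,Diomedeidae,Southern Royal Albatross,AMNH 1437,S
31,Diomedea immutabilis,Procellariiformes,Diomedeidae,Laysan Albatross,MCZ 343050,S
32,Esacus giganteus,Charadriiformes,Burhinidae,Beach Stone-curlew,MV B6587,CF
33,Eudyptes chryosolophus,Sphenisciformes,Spheniscidae,Macaroni Penguin,YPM 102975,SUB
34,Eudyptes chrysocome,Sphenisciformes,Spheniscidae,Western Rockhopper Penguin,MCZ 346428,SUB
35,Eurostopodus mystacalis,Caprimulgiformes,Caprimulgidae,White-throated Nightjar,MV W6663,FG
36,Falco peregrinus,Falconiformes,Falconidae,Peregrine Falcon,MV W3765,FG
37,Falco rusticolus,Falconiformes,Falconidae,Gyrfalcon,MCZ 343335,FG
38,Fulica atra,Gruiformes,Rallidae,Eurasian Coot,MV W6361,CF
39,Geranospiza caerulescens,Falconiformes,Accipitridae,Crane Hawk,MCZ 343032,S
40,Grallina cyanoleuca,Passeriformes,Grallinidae,Magpie-lark,MV B11122,IB
41,Guttera plumifera,Galliformes,Numididae,Plumed Guineafowl,AMNH 6415,PF
42,Gymnorhina tibicen,Passeriformes,Cracticidae,Australian Magpie,MV B6540,FG
43,Herpetotheres cachinnans,Falconiformes,Falconidae,Laughing Falcon,MCZ 337109,FG
44,Hirundapus caudacutus,Apodiformes,Apodidae,White-throated Needletail,MV B11129,S
45,Larus novaehollandiae,Charadriiformes,Lariidae,Silver Gull,MV W6163,FG
46,Leipoa ocellata,Galliformes,Megapodiidae,Malleefowl,MV B9276,PF
47,Leptoptilos dubius,Ciconiiformes,Ciconiidae,Greater Adjutant,MV W5083,S
48,Limosa lapponica,Charadriiformes,Scolopacidae,Bar-tailed Godwit,MV W4133,CF
49,Macrocephalon maleo,Galliformes,Megapodidae,Maleo,MCZ 340355,PF
50,Megaceryle torquata,Coraciiformes,Cerylidae,Ringed Kingfisher,YPM 109939,FG
51,Menura novaehollandiae,Passeriformes,Menuridae,Superb Lyrebird,MV B12391,PF
52,Momotus momota,Coraciiformes,Momotidae,Blue-crowned Motmot,MV 31795,CF
53,Morus bassanus,Pelecaniformes,Sulidae,Northern Gannet,MCZ 347043,S
54,Morus serrator,Pelecaniformes,Sulidae,Australasian Gannet,MV W4734,S
55,Mycteria americana,Ciconiiformes,Ciconiidae,Wood Stork,AMNH 3768,S
56,Ninox novaeseelandiae,Strigiformes,Strigidae,Southern Boobook,MV B11547,FG
57,Numenius arquata,Charadriiformes,Scolopacidae,Eurasian Curlew,YPM 111466,CF
58,Numida meleagris,Galliformes,Numididae,Helmeted Guineafowl,MV W6355,PF
59,Oriolus sagittatus,Passeriformes,Oriolidae,Olive-backed Oriole,MV B8562,IB
60,Oxyura australis,Anseriformes,Anatidae,Blue-billed Duck,MV B5145,CF
61,Pagodroma nivea,Procellariiformes,Oceanitidae,Snow Petrel,MV R6590,FG
62,Pandion haliaetus,Falconiformes,Accipitridae,Osprey,MCZ 347607,S
63,Pelecanoides urinatrix,Procellariiformes,Pelecanoididae,Common Diving-petrel,MV B6759,CF
64,Phaethon rubricauda,Phaethontiformes,Phaethontidae,Red-tailed Tropicbird,YPM 110024,FG
65,Phalacrocorax carbo,Pelecaniformes,Phalacrocoracidae,Great Cormorant,MV W6577,CF
66,Phaps elegans,Columbiformes,Columbidae,Brush Bronzewing,MV B8568,CF
67,Phoenicopterus ruber,Phoenicopteriformes,Phoenicopteridae,American Flamingo,MV 8748,CF
68,Podargus strigoides,Caprimulgiformes,Podargidae,Tawny Frogmouth,MV B6595,FG
69,Podiceps cristatus,Podicipediformes,Podicipedidae,Great Crested Grebe,MV W4196,CF
70,Pterodroma macroptera,Procellariiformes,Procellariidae,Great-winged Petrel,MV B10118,S
71,Ptilonorhynchus violaceus,Passeriformes,Ptilonorhynchidae,Satin Bowerbird,MV W6490,CF
72,Pulsatrix perspicellata,Strigiformes,Strigidae,Spectacled Owl,MCZ 343002,FG
73,Recurvirostra novaehollandiae,Charadriiformes,Recurvirostridae,Red-necked Avocet,MV W6194,FG
74,Rostratula benghalensis,Charadriiformes,Rostratulidae,Greater Painted Snipe,MV B1196,CF
75,Rynchops niger,Charadriiformes,Rynchopidae,Black Skimmer,YPM 107666,CF
76,Sagittarius serpentarius,Falconiformes,Sagittariidae,Secretarybird,AMNH 4006,FG
77,Spheniscus humboldti,Sphenisciformes,Spheniscidae,Humboldt Penguin,MCZ 347040,SUB
78,Stercorarius skua,Charadriiformes,Stercorariidae,Great Skua,MV W6658,CF
79,Stiltia isabella,Charadriiformes,Glareolidae,Australian Pratincole,MV B8534,CF
80,Sturnus vulgaris,Passeriformes,Sturnidae,European Starling,MV B12039,IB
81,Thalassarche chrysostoma,Procellariiformes,Diomedeida,Grey-headed Albatross,MV B6731,S
82,Threskiornis spinicollis,Ciconiiformes,Plataleidae,Straw-necked Ibis,MV W3973,FG
83,Tinamus major,Tinamiformes,Tinamidae,Great Tinamou,MCZ 342774,PF
84,Tityra semifasciata,Passeriformes,Cotingidae,Masked Tityra,MV B10711,IB
85,Tyrannus melancholicus,Passeriformes,Tyrannidae,Tropical Kingbird,MV B10637,IB
86,Tyto alba,Strigiformes,Tytonidae,Barn Owl,MV B11415,FG
87,Vanellus miles,Charadriiformes,Charadriidae,Masked Lapwing,MV W1350,CF
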