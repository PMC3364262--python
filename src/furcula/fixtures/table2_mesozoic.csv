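no,genus,clade,age,specimen_id
88,Archaeopteryx,Basal Aves,Late Jurassic,BMNH 37001
89,Cathayornis,Enantiornithes,Early Cretaceous,IVPP V9769
91,Concornis,Enantiornithes,Early Cretaceous,LH 2814
92,Confuciusornis,Basal Aves,Early Cretaceous,GMV 2133
93,Eoalulavis,Enantiornithes,Early Cretaceous,LH 13500a
94,Eoconfuciusornis,Basal Aves,Early Cretaceous,IVPP V11977
95,Hongshanornis,Ornithuromorpha,Early Cretaceous,IVPP V14533
96,Iberomesornis,Enantiornithes,Early Cretaceous,LH 22
97,Longicrusavis,Ornithuromorpha,Early Cretaceous,PKUP V1069
98,Longipteryx,Enantiornithes,Early Cretaceous,IVPP V12325
99,Noguerornis,Enantiornithes,Early Cretaceous,LP 715 IEI
100,Ornithuromorpha gen et sp indet,Ornithuromorpha,Early Cretaceous,FRDC-05-CM-021
101,Pengornis,Enantiornithes,Early Cretaceous,IVPP V15336
102,Protopteryx,Enantiornithes,Early Cretaceous,IVPP V11665
103,Rapaxavis,Enantiornithes,Early Cretaceous,DNHM D2522
104,Sapeornis,Basal Aves,Early Cretaceous,IVPP V13276
105,Vescornis,Enantiornithes,Early Cretaceous,NIGP 130722
106,Zhongjianornis,Basal Aves,Early Cretaceous,IVPP V15900
108,Gansus,Ornithuromorpha,Early Cretaceous,CAGM CM003
109,Anchiornis,Paraves,Early Cretaceous,LPM B00169
110,Bambiraptor,Dromaeosauridae,Late Cretaceous,AMNH FR30554
111,Falcarius,Therizinosauria,Early Cretaceous,UMNH-VP 14671
112,Neimongosaurus,Therizonosauria,Late Cretaceous,LH V0001
113,Oviraptor,Oviraptoridae,Late Cretaceous,AMNH FR 6517
114,Tyrannosaurus,Tyrannosauridae,Late Cretaceous,MOR 1125
115,Velociraptor,Dromaeosauridae,Late Cretaceous,IGM 100/976
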