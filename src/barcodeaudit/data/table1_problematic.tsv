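# Problematic identifications of the Volga butterfly audit: the 45 published
# specimen rows, with abbreviated genus names expanded and indeterminate
# ("sp.") entries omitted from the machine-readable conflict column.
# geographic_correction_printed reproduces the published column verbatim.
# cluster_id encodes the published clustering: conspecific specimen pairs
# share a cluster except the two deeply diverged Hyponephele lycaon
# haplotypes (7.2% apart), which fall in two clusters.
query_id	morphology_label	majority_id	other_ids_with_similarity	final_id	final_rank	confidence_pct	categories	geographic_correction_printed	cluster_id
EY010	Aglais io	Aglais io	Vanessa cardui (100.00)	Aglais	genus	83	CROSS_GENUS_CONTAMINATION	N/A	C_aglais_io
EY029	Apatura ilia	Apatura ilia	Apatura metis (99.53)	Apatura	genus	100	UNDIFFERENTIATED	No	C_apatura_ilia
EY092	Apatura ilia	Apatura ilia	Apatura metis (99.69)	Apatura	genus	100	UNDIFFERENTIATED	No	C_apatura_ilia
EY096	Aphantopus hyperantus	Aphantopus hyperantus	Aphantopus bieti (99.68)	Aphantopus	genus	100	SPECIES_MISLABEL	N/A	C_aphantopus
EY033	Araschnia levana	Araschnia levana	Boloria selene (100.00); Polygonia c-album (100.00)	Araschnia levana	species	92	CROSS_GENUS_CONTAMINATION	N/A	C_araschnia
EY014	Argynnis paphia	Argynnis paphia	Polyommatus icarus (100.00)	Argynnis paphia	species	96	CROSS_GENUS_CONTAMINATION	N/A	C_argynnis_paphia
EY126	Aricia artaxerxes	Aricia artaxerxes	Plebejus argus (100.00)	Aricia artaxerxes	species	96	CROSS_GENUS_CONTAMINATION	N/A	C_aricia
EY108	Brenthis ino	Brenthis ino	Melitaea athalia (99.84); Brenthis daphne (99.68)	Brenthis ino	species	92	SPECIES_MISLABEL;CROSS_GENUS_CONTAMINATION	N/A	C_brenthis
EY063	Callophrys rubi	Callophrys rubi	Callophrys chalybeitincta (100.00); Novosatsuma collosa (99.84)	Callophrys	genus	83	UNDIFFERENTIATED	No	C_callophrys
EY105	Carcharodus alceae	Carcharodus alceae	Erynnis tages (99.53)	Carcharodus alceae	species	96	CROSS_GENUS_CONTAMINATION	N/A	C_carcharodus
EY135	Carcharodus alceae	Carcharodus alceae	Carcharodus floccifera (100.00); Carcharodus stauderi (100.00)	Carcharodus	genus	100	SPECIES_MISLABEL	N/A	C_carcharodus
EY048	Carterocephalus palaemon	Carterocephalus palaemon	Carterocephalus silvicola (99.52)	Carterocephalus palaemon	species	92	SPECIES_MISLABEL	N/A	C_carterocephalus
EY036	Coenonympha arcania	Coenonympha arcania	Coenonympha leander (99.68); Coenonympha orientalis (99.36)	Coenonympha arcania	species	96	UNDIFFERENTIATED	No	C_coen_arcania
EY038	Coenonympha pamphilus	Coenonympha pamphilus	Coenonympha lyllus (100.00)	Coenonympha pamphilus	species	92	TAXONOMY_UNCERTAINTY	N/A	C_coen_pamphilus
EY100	Colias erate	Colias crocea, Colias erate	Colias crocea (100.00); Colias marnoana (100.00); Colias poliographus (99.84)	Colias	genus	100	UNDIFFERENTIATED	No	C_colias_erate
EY058	Colias myrmidone	Colias myrmidone	Colias caucasica (100.00)	Colias	genus	100	UNDIFFERENTIATED	Yes	C_colias_myrmidone
EY076	Cupido minimus	Cupido minimus	Cupido tusovi (99.84); Cupido osiris (99.84); Glaucopsyche lycormas (99.69)	Cupido	genus	100	SPECIES_MISLABEL;TAXONOMY_UNCERTAINTY	N/A	C_cupido_minimus
EY134	Cupido osiris	Cupido osiris	Cupido staudingeri (98.87)	Cupido	genus	100	UNDIFFERENTIATED	N/A	C_cupido_osiris
EY116	Cyaniris semiargus	Cyaniris semiargus	Glaucopsyche lycormas (100.00)	Cyaniris semiargus	species	92	SPECIES_MISLABEL;CROSS_GENUS_CONTAMINATION	N/A	C_cyaniris
EY099	Davidina tarpeia	Davidina tarpeia	Davidina dzhulukuli (100.00); Davidina lederi (99.66)	Davidina	genus	100	UNDIFFERENTIATED	Yes	C_davidina
EY104	Erynnis tages	Erynnis tages	Colias alfacariensis (100.00)	Erynnis tages	species	96	CROSS_GENUS_CONTAMINATION	N/A	C_erynnis
EY056	Euchloe ausonia	Euchloe ausonia	Euchloe pulverata (99.69); Euchloe persica (99.67); Euchloe ochracea (98.44)	Euchloe	genus	100	SPECIES_MISLABEL;TAXONOMY_UNCERTAINTY	N/A	C_euchloe
EY115	Fabriciana niobe	Fabriciana niobe	Fabriciana adippe (100.00); Fabriciana xipe (100.00)	Fabriciana	genus	100	SPECIES_MISLABEL	N/A	C_fabriciana
EY138	Hyponephele lycaon	Hyponephele lycaon	Hyponephele przhewalskyi (100.00); Coenonympha pamphilus (99.84)	Hyponephele lycaon	species	92	TAXONOMY_UNCERTAINTY;CROSS_GENUS_CONTAMINATION	N/A	C_hyponephele_1
EY139	Hyponephele lycaon	different taxa		Satyrinae	subfamily	100	ANOMALOUS_BARCODE	N/A	C_hyponephele_2
EY040	Iphiclides podalirius	Iphiclides podalirius	Iphiclides feistahameli (100.00)	Iphiclides	genus	100	UNDIFFERENTIATED	Yes	C_iphiclides
EY054	Leptidea sinapis	Leptidea sinapis	Leptidea descimoni (99.84)	Leptidea sinapis	species	92	SPECIES_MISLABEL	N/A	C_leptidea
EY136	Lysandra coridon	Lysandra coridon	Hipparchia semele (100.00)	Lysandra coridon	species	96	CROSS_GENUS_CONTAMINATION	N/A	C_lysandra
EY107	Melitaea arduinna	Melitaea arduinna	Melitaea cinxia (100.00)	Melitaea arduinna	species	91	SPECIES_MISLABEL	N/A	C_mel_arduinna
EU002	Melitaea britomartis	Melitaea britomartis	Melitaea aurelia (99.84)	Melitaea	genus	100	SPECIES_MISLABEL	N/A	C_mel_britomartis
EY028	Melitaea phoebe	Melitaea phoebe	Melitaea sibina (99.84); Melitaea ornata (99.69)	Melitaea	genus	100	UNDIFFERENTIATED	No	C_mel_phoebe
MA274	Muschampia proteides	Muschampia proteides	Muschampia proto (100.00); Muschampia sovietica (100.00)	Muschampia	genus	100	TAXONOMY_UNCERTAINTY	N/A	C_muschampia
MA275	Muschampia proteides	Muschampia proteides	Muschampia proto (100.00); Muschampia sovietica (100.00)	Muschampia	genus	100	TAXONOMY_UNCERTAINTY	N/A	C_muschampia
EY004	Neptis sappho	Neptis sappho	Araschnia levana (100.00)	Neptis sappho	species	94	CROSS_GENUS_CONTAMINATION	N/A	C_neptis
EY045	Ochlodes sylvanus	Ochlodes sylvanus	Ochlodes hyrcana (100.00)	Ochlodes	genus	100	TAXONOMY_UNCERTAINTY	N/A	C_ochlodes
EY093	Papilio machaon	Papilio machaon	Papilio saharae (99.52)	Papilio machaon	species	92	UNDIFFERENTIATED	Yes	C_papilio
EY035	Pararge aegeria	Pararge aegeria	Argynnis paphia (100.00)	Pararge aegeria	species	95	CROSS_GENUS_CONTAMINATION	N/A	C_pararge
EY052	Pieris napi	Pieris napi	Pieris rapae (100.00)	Pieris napi	species	92	SPECIES_MISLABEL	N/A	C_pieris
2022MA269s	Plebejus idas	Plebejus idas	Plebejus argus (100.00); Plebejus bellieri (99.84)	Plebejus	genus	100	SPECIES_MISLABEL	N/A	C_plebejus
EY031	Polygonia c-album	Polygonia c-album	Polygonia interposita (100.00); Aglais io (100.00)	Polygonia	genus	80	TAXONOMY_UNCERTAINTY;CROSS_GENUS_CONTAMINATION	N/A	C_polygonia
EY142	Polyommatus damocles	different taxa		Polyommatus	genus	100	DB_INCOMPLETE	N/A	C_poly_damocles
EY069	Polyommatus icarus	Polyommatus icarus	Polyommatus juno (99.69)	Polyommatus icarus	species	96	TAXONOMY_UNCERTAINTY	Yes	C_poly_icarus
EY085	Pontia edusa	Pontia edusa	Pontia daplidice (100.00)	Pontia	genus	100	SPECIES_MISLABEL	N/A	C_pontia
EY127	Pontia edusa	Pontia edusa	Pontia daplidice (100.00)	Pontia	genus	100	SPECIES_MISLABEL	N/A	C_pontia
EY046	Pyrgus malvae	Pyrgus malvae	Pyrgus malvoides (99.22)	Pyrgus	genus	100	UNDIFFERENTIATED	Yes	C_pyrgus
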