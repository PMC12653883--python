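# Ranges of the species conflicting with the undifferentiated-barcode rows,
# relative to the focal Volga region (code VLG).  Region codes are opaque.
species	regions
Apatura metis	VLG;BLK
Callophrys chalybeitincta	VLG;CAU
Novosatsuma collosa	EAS
Coenonympha leander	VLG;BLK
Coenonympha orientalis	BLK
Colias crocea	VLG;MED
Colias marnoana	AFR
Colias poliographus	EAS
Colias caucasica	BLK
Cupido staudingeri	CAS
Davidina dzhulukuli	ALT
Davidina lederi	MNG
Iphiclides feistahameli	IBE
Melitaea sibina	CAS
Melitaea ornata	VLG;MED
Papilio saharae	AFR
Pyrgus malvoides	IBE
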