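section	id_a	id_b	group_a	group_b	length_aa	identity_pct	reported_rate_1e9	note
Pho88	Pho88_Ppatens	Pho88_Spombe	Plants	Fungi	154	26.8	0.420
Pho88	Pho88_Ppatens	Pho88_Ccinereus	Plants	Fungi	151	23.1	0.445
Pho88	Pho88_Ppatens	Pho88_Pchrysosporium	Plants	Fungi	151	25.0	0.428
Pho88	Pho88_Ppatens	Pho88_Cneoformans	Plants	Fungi	152	20.1	0.521
Pho88	Pho88_Ccinereus	Pho88_Pchrysosporium			151	64.9		no_time
Pho88	Pho88_Ccinereus	Pho88_Cneoformans	Agaricomycetes	Tremellomycetes	151	51.3	0.472
Pho88	Pho88_Pchrysosporium	Pho88_Cneoformans	Agaricomycetes	Tremellomycetes	151	58.6		nd
uapA	uapA_Ppatens	uapA_Agossypii	Plants	Fungi	466	40.7	0.266
uapA	uapA_Ppatens	uapA_Ccinereus	Plants	Fungi	456	38.4	0.288
uapA	uapA_Ppatens	uapA_Pchrysosporium	Plants	Fungi	391	43.6	0.263
uapA	uapA_Ppatens	uapA_Cneoformans	Plants	Fungi	472	36.9	0.318
uapA	uapA_Ccinereus	uapA_Pchrysosporium			391	67.9		no_time
uapA	uapA_Ccinereus	uapA_Cneoformans	Agaricomycetes	Tremellomycetes	456	39.6	0.560
uapA	uapA_Pchrysosporium	uapA_Cneoformans	Agaricomycetes	Tremellomycetes	391	43.2		nd
Tcn1	Tcn1_Cneoformans	Ccchromovir1_Ccinereus	Tremellomycetes	Agaricomycetes	684	53.6	0.441
Tcn1	Tcn1_Cneoformans	PcMetavir6_Pchrysosporium	Tremellomycetes	Agaricomycetes	684	52.2		nd
Tcn1	Tcn1_Cneoformans	BatDenTy3-1_Bdendrobatidis	Homobasidiomycetes	Chytridiomycetes	677	49.1	0.381
Tcn1	PcMetavir6_Pchrysosporium	Ccchromovir1_Ccinereus			688	72.4		no_time
Tcn1	PcMetavir6_Pchrysosporium	BatDenTy3-1_Bdendrobatidis	Homobasidiomycetes	Chytridiomycetes	677	47.0	0.412
Tcn1	BatDenTy3-1_Bdendrobatidis	Ccchromovir1_Ccinereus	Homobasidiomycetes	Chytridiomycetes	677	46.5	0.411
Tcn1	Tcn1_Cneoformans	PpatensLTR1_Ppatens	Fungi	Plants	675	52.0	0.216	ht
Tcn1	Tcn1_Cneoformans	SM-Tcn1_Smoellendorffii	Fungi	Plants	682	50.3	0.235	ht
Tcn1	PcMetavir6_Pchrysosporium	PpatensLTR1_Ppatens	Fungi	Plants	675	51.8	0.217	ht
Tcn1	PcMetavir6_Pchrysosporium	SM-Tcn1_Smoellendorffii	Fungi	Plants	682	49.5	0.230	ht
Tcn1	PpatensLTR1_Ppatens	SM-Tcn1_Smoellendorffii			675	58.6	0.429	no_time
Pyggy	PyrTriTy3-2_Ptriticirepentis	NecHaemTy3-4_Nhaematococca	Dothideomycetes	Sordariomycetes	706	77.0	0.259	ht
Pyggy	PyrTriTy3-2_Ptriticirepentis	ChaGloTy3-8_Cglobosum	Dothideomycetes	Sordariomycetes	706	48.5	0.706
Pyggy	PyrTriTy3-2_Ptriticirepentis	grh_Mgrisea	Dothideomycetes	Sordariomycetes	701	49.2	0.703
Pyggy	PyrTriTy3-2_Ptriticirepentis	Dane4_Anidulans			695	55.5	0.531	no_time
Pyggy	AltBraTy3-2_Abrassicicola	NecHaemTy3-4_Nhaematococca	Dothideomycetes	Sordariomycetes	709	47.7	0.880	irreproducible
Pyggy	AltBraTy3-2_Abrassicicola	Dane4_Anidulans			695	49.2	0.649	no_time
Pyggy	grh_Mgrisea	Dane4_Anidulans	Sordariomycetes	Eurotiomycetes	695	48.5	0.670
Pyret	skippy_Foxysporum	PyrTriTy3-1_Ptriticirepentis	Sordariomycetes	Dothideomycetes	648	40.4	0.772	irreproducible
Pyret	skippy_Foxysporum	AFLAV_Aflavus	Sordariomycetes	Eurotiomycetes	673	41.4	0.766
Pyret	AFLAV_Aflavus	PyrTriTy3-1_Ptriticirepentis			648	44.3	0.656	no_time
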