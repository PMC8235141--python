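SPECIES	LOCALITY	VOUCHER	H3	16S	COI
Aeolidiella alderi (Cocks, 1852)	Italy	ZSMMol20012341	HQ616795	HQ616766	HQ616729
Aeolidiella sanguinea (Norman, 1877)	France (Atlantic Ocean)	MNCN/ADN51932	JX087600	JX087538	JX087466
Babakina anadoni (Ortea, 1979)	Brazil	MNRJ10893	HQ616775	HQ616709	HQ616746
Babakina anadoni (Ortea, 1979)	Galicia, Spain	MNCN15.05/46704	HQ616796	HQ616730	HQ616767
Babakina indopacifica Gosliner, Gonzalez-Duarte & Cervera, 2007	Luzon, Batangas, Philippines	CASIZ177458	HM162587	HM162678	HM162754
Dicata odhneri Schmekel, 1967	Ballanera, Algesiras, Spain	BAU2674	LT596569	LT596549	LT596560
Dicata odhneri Schmekel, 1967	Andalusia, Spain	MNCN15.05/53692		HQ616739	HQ616773
Dondice banyulensis Portmann & Sandmeier, 1960	Djerba, Tunisia	RM3_129	LS483284	LS483274	LS483267
Dondice banyulensis Portmann & Sandmeier, 1960	Argentario, Tuscany, Italy	RM3_356	LS483285	LS483275	LS483268
Dondice banyulensis Portmann & Sandmeier, 1960	Sant'Agostino, Latium, Italy	RM3_290	LS483286	LS483276	LS483269
Dondice banyulensis Portmann & Sandmeier, 1960		Db_60		GQ403751	GQ403773
Dondice occidentalis (Engel, 1925)	Exuma, Bahamas	LACM177715	KC526529	KC526510	
Dondice occidentalis (Engel, 1925)		LACM2003-41.5	JQ699394	JQ699482	JQ699570
Dondice occidentalis (Engel, 1925)	Exuma, Bahamas	D252	KC526527	KC526518	
Dondice occidentalis (Engel, 1925)	Jamaica	JG61	KC526534	KC526512	
Dondice parguerensis Brandon & Cutress, 1985	La Parguera, Puerto Rico	LACM177705	KC526535	KC526520	
Dondice trainitoi Furfaro & Mariottini, 2020	Civitavecchia, Latium, Italy	RM3_425	LS483287	LS483277	LS483270
Dondice trainitoi Furfaro & Mariottini, 2020	Civitavecchia, Latium, Italy	RM3_596	LS483288	LS483278	LS483271
Godiva quadricolor (Barnard, 1927)	Sabaudia, Latium, Italy	RM3_117	LS483289	LS483279	MG546001
Godiva quadricolor (Barnard, 1927)	Sabaudia, Latium, Italy	RM3_153	LS483290	LS483280	MG546002
Godiva quadricolor (Barnard, 1927)	Sabaudia, Latium, Italy	RM3_154	LS483291	LS483281	MG546003
Godiva quadricolor (Barnard, 1927)	Knysna Lagoon, South Africa	CASIZ176385	HM162589	HM162680	HM162756
Hermissenda opalescens	Monterey Bay, CA, USA	isolate_TL270	KU950225	KU950130	KU950196
Hermissenda opalescens	Malibu, CA, USA	isolate_TL275	KU950224	KU950129	KU950195
Hermissenda opalescens	Long Beach, CA, USA	isolate_TL269	KU950222	KU950128	KU950193
Hermissenda emurai	Tateyama-Chiba, Japan	isolate_TL185	KU950215	KU950123	KU950186
Hermissenda emurai	Tateyama-Chiba, Japan	isolate_TL184	KU950214	KU950122	KU950185
Hermissenda crassicornis	Victoria, B.C., Canada	isolate_TL200	KU950210	KU950118	KU950174
Hermissenda crassicornis	Victoria, B.C., Canada	isolate_TL204	KU950212	KU950121	KU950178
Nanuca sebastiani			JQ699469	JQ699557	JQ699633
Phyllodesmium briareum (Bergh, 1896)	Batangas, Philippines	CASIZ 177239	HQ010460	HQ010528	HQ010492
Phyllodesmium colemani Rudman, 1991	Batangas, Philippines	CASIZ 177647	HQ010466	HQ010534	HQ010498
Phyllodesmium crypticum Rudman, 1981	Batangas, Philippines	CASIZ 180381	HQ010477	HQ010543	HQ010507
Phyllodesmium horridum (Macnae, 1954)	Cape Region, South Africa	CASIZ176127	HM162590	HM162681	HM162757
Phyllodesmium hyalinum Ehrenberg, 1831		Phy.orig.		GQ403756	GQ403778
Phyllodesmium jakobsenae Burghardt & Wagele, 2004	Batangas, Philippines	CASIZ 177576	HQ010456	HQ010524	HQ010489
Phyllodesmium karenae Moore & Gosliner, 2009	Batangas, Philippines	CASIZ 180384	HQ010478	HQ010544	HQ010508
Phyllodesmium koehleri Burghardt, Schrodl & Wagele, 2008	Batangas, Philippines	CASIZ 177693	HQ010462	HQ010530	HQ010494
Phyllodesmium lizardensis Burghardt, Schrodl & Wagele, 2008	Batangas, Philippines	CASIZ 180382	HQ010474	HQ010540	HQ010505
Phyllodesmium macphersonae (Burn, 1962)	Batangas, Philippines	CASIZ 177493	HQ010453	HQ010522	HQ010487
Phyllodesmium opalescens Rudman, 1991	Batangas, Philippines	CASIZ 177541	HQ010450	HQ010519	HQ010485
Phyllodesmium parangatum Ortiz & Gosliner, 2003	Batangas, Philippines	CASIZ 180383B	HQ010476	HQ010542	HQ010506
Phyllodesmium poindimiei (Risbec, 1928)	Batangas, Philippines	CASIZ 177783	HQ010463	HQ010531	HQ010495
Phyllodesmium rudmani Burghardt & Gosliner, 2006	Batangas, Philippines	CASIZ 177622	HQ010461	HQ010529	HQ010493
Phyllodesmium tuberculatum Moore & Gosliner, 2009	Batangas, Philippines	CASIZ 177663	HQ010465	HQ010533	HQ010497
Duvaucelia striata Haefelfinger, 1963	Giannutri Is., Tuscany, Italy	BAU2695	LT615407	LT596542	LT596540
Duvaucelia striata Haefelfinger, 1963	Formiche Is., Tuscany, Italy	BAU2696	LT615408	LT596543	LT596541
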