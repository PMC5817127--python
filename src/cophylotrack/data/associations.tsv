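symbiont_tip	species	host	locality	date
EN01	E. binotata	Sideroxylon lycioides	Moulton, AL	2004-05-26
EN02	E. binotata	Sideroxylon lanuginosum	Van Buren, MO	2006-04-30
EN03	E. binotata	Sideroxylon lanuginosum	Austin, TX	2007-04-01
EN04	E. binotata	Carya	Mooresville, IN	2004-06-11
EN05	E. binotata	Carya	Cloud Crossing, LA	2003-04-27
EN06	E. binotata	Celastrus scandens	Columbia, MO	2002-07-01
EN07	E. binotata	Celastrus scandens	Ithaca, NY	2002-07-06
EN08	E. binotata	Celastrus scandens	Stone Valley, PA	2003-06-04
EN09	E. binotata	Cercis canadensis	Chinnabee, AL	2003-05-01
EN10	E. binotata	Cercis canadensis	Rutledge, GA	2003-05-07
EN11	E. binotata	Cercis canadensis	Effingham, IL	2003-05-21
EN12	E. binotata	Cercis canadensis	Woodmont, MD	2003-06-07
EN13	E. binotata	Cercis canadensis	Columbia, MO	2002-06-01
EN14	E. binotata	Cercis canadensis	Tupelo, MS	2003-04-29
EN15	E. binotata	Cercis canadensis	New Buffalo, PA	2002-07-09
EN16	E. binotata	Cercis canadensis	Parksville, TN	2003-05-03
EN17	E. binotata	Cercis canadensis	Grafton, WV	2003-06-06
EN18	E. binotata	Dirca palustris	Bloomingdale, IN	2004-08-15
EN19	E. binotata	Dirca palustris	White Lake, ON	2004-07-01
EN20	Enchenopa species	Unknown	Guatemala City, Guatemala	1999-12-20
EN21	Enchenopa species	Unknown	Gracias, Honduras	2001-07-22
EN22	Enchenopa species	Unknown	Juticalpa, Honduras	2001-07-24
EN23	Enchenopa species	Unknown	Lucerna, Honduras	2001-07-21
EN24	Enchenopa species	Unknown	La Union, Honduras	2001-07-25
EN25	Enchenopa species	Unknown	Bambito, Panama	2000-01-18
EN26	Enchenopa species	Composite	Boquete, Panama	1998-03-06
EN27	Enchenopa species	Unknown	Panama	2000-01-01
EN28	Enchenopa species	Diphysa robinoides	Pedasi, Panama	2000-02-13
EN29	Enchenopa species	Unknown	Gamboa, Panama	2000-01-21
EN30	Enchenopa species	Unknown	La Union, Mexico	2001-10-24
EN31	Enchenopa species	Unknown	La Huerta, Mexico	2001-10-16
EN32	Enchenopa species	Unknown	Veracruz, Mexico	2007
EN33	Enchenopa species	Unknown	Veracruz, Mexico	2007
EN34	Enchenopa species	Unknown	Tegucigalpa, Honduras	2001-07-24
EN35	Enchenopa species	Unknown	Trinidad, Honduras	2001-07-29
EN36	Enchenopa species	Unknown	Chiriqui Grande, Panama	1998-03-05
EN37	E. binotata	Juglans cinerea	Bangor, NY	1997-08-30
EN38	E. binotata	Juglans cinerea	Ithaca, NY	1996-06-16
EN39	E. binotata	Juglans nigra	Woodmont, MD	2003-06-07
EN40	E. binotata	Juglans nigra	Columbia, MO	2002-07-01
EN41	E. binotata	Liriodendron tulipifera	Ithaca, NY	2002-07-16
EN42	E. binotata	Liriodendron tulipifera	Oxford, OH	2004-06-14
EN43	E. binotata	Liriodendron tulipifera	Harveysburg, OH	2004-06-14
EN44	E. binotata	Ptelea trifoliata	Yorkville, IL	2004-06-03
EN45	E. binotata	Ptelea trifoliata		2002-06-01
EN46	E. binotata	Ptelea trifoliata	Columbia, MO	2002-06-01
EN47	E. binotata	Robinia pseudoacacia	Woodmont, MD	2003-06-07
EN48	E. binotata	Robinia pseudoacacia	Columbia, MO	2002-07-01
EN49	E. binotata	Robinia pseudoacacia	Ithaca, NY	2002-07-06
EN50	E. binotata	Robinia pseudoacacia	Stone Valley, PA	2003-06-04
EN51	E. binotata	Viburnum cassinoides	Cherry Lane, NC	2003-06-05
EN52	E. binotata	Viburnum cassinoides	Davis, WV	2003-06-06
EN53	E. binotata	Viburnum lentago	Bernheim, KY	2002-06-01
EN54	E. binotata	Viburnum lentago	Ridgeway, PA	2003-06-05
EN55	E. binotata	Viburnum prunifolium	Columbia, MO	2002-06-27
EN56	E. binotata	Viburnum prunifolium	Stone Valley, PA	2003-06-04
EN57	E. binotata	Viburnum prunifolium	Amherst, VA	2003-06-06
EN58	E. binotata	Viburnum rufidulum	Rutledge, GA	2003-05-07
EN59	E. binotata	Viburnum rufidulum	Columbia, MO	2003-06-01
EN60	E. binotata	Viburnum rufidulum	Greenville, SC	2003-05-08
EN61	E. binotata	Viburnum rufidulum	Nashville, TN	2003-05-02
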