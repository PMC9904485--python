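label,ecotone,location,rate_low,rate_high,in_mean_a,in_mean_b,note
texas_grassland,grassland->forest,Southern Texas USA,1.8,3.2,1,0,mean range of clump growth
makaba,savanna->forest,Mayombe Rep. of Congo,0.14,0.28,1,1,Makaba site
kwilila,savanna->forest,Mayombe Rep. of Congo,0.27,0.75,1,1,Kwilila site
coastal_gabon,savanna->forest,Coastal Gabon,1,1,1,1,
coastal_congo_aerial,savanna->forest,Coastal Rep. of Congo,1,1,1,1,aerial imagery
coastal_congo_growth,savanna->forest,Coastal Rep. of Congo,1,2,1,1,diametrical growth model
cameroon_akonolinga,savanna->forest,Central Cameroon,0.6,0.6,1,1,north of Akonolinga
cameroon_bertoua,savanna->forest,Central Cameroon,1.2,1.2,1,1,between Bertoua and Batouri
cameroon_mbam,savanna->forest,Central Cameroon,2,2,1,1,confluence of Mbam and Kim
cameroon_lower,savanna->forest,Central Cameroon,0.25,0.25,1,1,lower bound
nigeria_typical,savanna->forest,Western Nigeria,3.4,3.4,1,1,typical boundary
nigeria_atypical,savanna->forest,Western Nigeria,33,33,0,0,atypical map-derived boundary
cote_divoire,savanna->forest,Cote d'Ivoire,2.5,3.5,1,1,decade-plus record
french_guiana_palm,mixed->locally abundant,Central French Guiana,2.3,2.3,1,0,understory palm front
ituri_prior,mixed->monodominant,Ituri DRC,0.34,0.34,0,0,earlier two-census estimate
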