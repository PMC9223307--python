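zone,year,land_class,area_km2
ALL,2000,construction land,47197
ALL,2000,cultivated land,638571
ALL,2000,grassland,341406
ALL,2000,unused land,21814
ALL,2000,water,57877
ALL,2000,woodland,938340
ALL,2005,construction land,52900
ALL,2005,cultivated land,632019
ALL,2005,grassland,339984
ALL,2005,unused land,21585
ALL,2005,water,59481
ALL,2005,woodland,939466
ALL,2010,construction land,57453
ALL,2010,cultivated land,627056
ALL,2010,grassland,339431
ALL,2010,unused land,21787
ALL,2010,water,59925
ALL,2010,woodland,939880
ALL,2015,construction land,68015
ALL,2015,cultivated land,619095
ALL,2015,grassland,339253
ALL,2015,unused land,21846
ALL,2015,water,61011
ALL,2015,woodland,937085
ALL,2020,construction land,82884
ALL,2020,cultivated land,607803
ALL,2020,grassland,327807
ALL,2020,unused land,21766
ALL,2020,water,63609
ALL,2020,woodland,940496
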