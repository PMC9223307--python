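land_class,service,coefficient
cultivated land,gas regulation,480.85
woodland,gas regulation,3365.95
grassland,gas regulation,769.36
water,gas regulation,0.0
unused land,gas regulation,0.0
construction land,gas regulation,0.0
cultivated land,climate regulation,855.91
woodland,climate regulation,2596.59
grassland,climate regulation,856.53
water,climate regulation,442.38
unused land,climate regulation,0.0
construction land,climate regulation,0.0
cultivated land,water conservation,577.02
woodland,water conservation,3077.44
grassland,water conservation,769.36
water,water conservation,19618.68
unused land,water conservation,28.85
construction land,water conservation,0.0
cultivated land,waste disposal,1577.19
woodland,waste disposal,1259.83
grassland,waste disposal,1259.83
water,waste disposal,17502.94
unused land,waste disposal,9.62
construction land,waste disposal,0.0
cultivated land,soil formation and protection,1404.08
woodland,soil formation and protection,3750.63
grassland,soil formation and protection,1875.32
water,soil formation and protection,9.62
unused land,soil formation and protection,19.23
construction land,soil formation and protection,0.0
cultivated land,biodiversity conservation,682.81
woodland,biodiversity conservation,3135.14
grassland,biodiversity conservation,1048.25
water,biodiversity conservation,2394.63
unused land,biodiversity conservation,326.98
construction land,biodiversity conservation,0.0
cultivated land,food production,961.7
woodland,food production,96.17
grassland,food production,288.51
water,food production,96.17
unused land,food production,9.62
construction land,food production,0.0
cultivated land,raw material,96.17
woodland,raw material,2500.42
grassland,raw material,48.08
water,raw material,9.62
unused land,raw material,0.0
construction land,raw material,0.0
cultivated land,entertainment,9.62
woodland,entertainment,1230.98
grassland,entertainment,38.47
water,entertainment,4173.78
unused land,entertainment,9.62
construction land,entertainment,0.0
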