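donor,recipient,richness,p_inv,observed
northwest_atlantic,north_baltic,570,0.16172,44
great_lakes_st_lawrence,north_baltic,320,0.04665,2
northeast_pacific,north_baltic,450,0.03669,17
northwest_pacific,north_baltic,1200,0.03509,49
ponto_caspian,north_baltic,500,0.00514,42
north_baltic,great_lakes_st_lawrence,250,0.04849,4
ponto_caspian,great_lakes_st_lawrence,500,0.00014,23
northwest_atlantic,great_lakes_st_lawrence,570,0.00006,10
northwest_pacific,great_lakes_st_lawrence,1200,0.00003,2
northeast_pacific,great_lakes_st_lawrence,450,0.00001,4
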