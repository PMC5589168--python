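product,batch,nominal_iu,nominal_ug,nominal_specific_activity_iu_mg,assay
Bemfola,PNS30388,300,22,13636,in_vivo_potency
Bemfola,PNS30230,450,33,13636,in_vivo_potency
Bemfola,PPS30400,150,11,13636,in_vivo_potency
Bemfola,PPS30021,75,5.5,13636,in_vivo_potency
Bemfola,PNS30390,150,11,13636,in_vivo_potency
Bemfola,PNS30228,225,16.5,13636,in_vivo_potency
Bemfola,PNS30389,225,16.5,13636,in_vivo_potency
Bemfola,PNS30229B,300,22,13636,in_vivo_potency
Bemfola,PNS30226,75,5.5,13636,glycopeptide_mapping
Bemfola,PPS30403,450,33,13636,glycopeptide_mapping
GONAL-f,199F005,300,22,13636,glycopeptide_mapping
GONAL-f,199F049,75,5.5,13636,glycopeptide_mapping
GONAL-f,199F051,75,5.5,13636,glycopeptide_mapping
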