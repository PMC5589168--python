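product,batch,block,class,percent
GONAL-f,199F005,antennarity,bi-antennary,76.2
GONAL-f,199F005,antennarity,tri-antennary,22.9
GONAL-f,199F005,antennarity,tetra-antennary,0.9
GONAL-f,199F005,fucosylation,a-fucosylated,97.8
GONAL-f,199F005,fucosylation,fucosylated,2.2
GONAL-f,199F005,sialylation,mono-sialylated,2.6
GONAL-f,199F005,sialylation,di-sialylated,84.0
GONAL-f,199F005,sialylation,tri-sialylated,13.4
GONAL-f,199F005,sialylation,tetra-sialylated,0.0
GONAL-f,199F049,antennarity,bi-antennary,76.9
GONAL-f,199F049,antennarity,tri-antennary,22.6
GONAL-f,199F049,antennarity,tetra-antennary,0.5
GONAL-f,199F049,fucosylation,a-fucosylated,97.8
GONAL-f,199F049,fucosylation,fucosylated,2.2
GONAL-f,199F049,sialylation,mono-sialylated,2.7
GONAL-f,199F049,sialylation,di-sialylated,85.5
GONAL-f,199F049,sialylation,tri-sialylated,11.8
GONAL-f,199F049,sialylation,tetra-sialylated,0.0
GONAL-f,199F051,antennarity,bi-antennary,77.8
GONAL-f,199F051,antennarity,tri-antennary,22.2
GONAL-f,199F051,antennarity,tetra-antennary,0.0
GONAL-f,199F051,fucosylation,a-fucosylated,97.6
GONAL-f,199F051,fucosylation,fucosylated,2.4
GONAL-f,199F051,sialylation,mono-sialylated,2.4
GONAL-f,199F051,sialylation,di-sialylated,85.7
GONAL-f,199F051,sialylation,tri-sialylated,11.9
GONAL-f,199F051,sialylation,tetra-sialylated,0.0
Bemfola,PPS30403,antennarity,bi-antennary,53.9
Bemfola,PPS30403,antennarity,tri-antennary,40.7
Bemfola,PPS30403,antennarity,tetra-antennary,5.3
Bemfola,PPS30403,fucosylation,a-fucosylated,98.8
Bemfola,PPS30403,fucosylation,fucosylated,1.2
Bemfola,PPS30403,sialylation,mono-sialylated,6.2
Bemfola,PPS30403,sialylation,di-sialylated,72.8
Bemfola,PPS30403,sialylation,tri-sialylated,21.0
Bemfola,PPS30403,sialylation,tetra-sialylated,0.8
Bemfola,PNS30226,antennarity,bi-antennary,52.7
Bemfola,PNS30226,antennarity,tri-antennary,41.8
Bemfola,PNS30226,antennarity,tetra-antennary,5.5
Bemfola,PNS30226,fucosylation,a-fucosylated,98.7
Bemfola,PNS30226,fucosylation,fucosylated,1.3
Bemfola,PNS30226,sialylation,mono-sialylated,6.8
Bemfola,PNS30226,sialylation,di-sialylated,71.8
Bemfola,PNS30226,sialylation,tri-sialylated,21.4
Bemfola,PNS30226,sialylation,tetra-sialylated,1.0
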