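product,batch,site,metric,value
GONAL-f,199F005,alpha_Asn52,z_number,211
GONAL-f,199F005,alpha_Asn52,a_index,225
GONAL-f,199F005,alpha_Asn78,z_number,175
GONAL-f,199F005,alpha_Asn78,a_index,212
GONAL-f,199F005,beta_Asn7,z_number,201
GONAL-f,199F005,beta_Asn7,a_index,367
GONAL-f,199F005,beta_Asn24,z_number,172
GONAL-f,199F005,beta_Asn24,a_index,209
GONAL-f,199F005,release_simulation,z_number,190
GONAL-f,199F005,release_simulation,a_index,253
GONAL-f,199F049,alpha_Asn52,z_number,209
GONAL-f,199F049,alpha_Asn52,a_index,224
GONAL-f,199F049,alpha_Asn78,z_number,174
GONAL-f,199F049,alpha_Asn78,a_index,211
GONAL-f,199F049,beta_Asn7,z_number,198
GONAL-f,199F049,beta_Asn7,a_index,368
GONAL-f,199F049,beta_Asn24,z_number,172
GONAL-f,199F049,beta_Asn24,a_index,208
GONAL-f,199F049,release_simulation,z_number,188
GONAL-f,199F049,release_simulation,a_index,253
GONAL-f,199F051,alpha_Asn52,z_number,210
GONAL-f,199F051,alpha_Asn52,a_index,222
GONAL-f,199F051,alpha_Asn78,z_number,177
GONAL-f,199F051,alpha_Asn78,a_index,211
GONAL-f,199F051,beta_Asn7,z_number,200
GONAL-f,199F051,beta_Asn7,a_index,367
GONAL-f,199F051,beta_Asn24,z_number,174
GONAL-f,199F051,beta_Asn24,a_index,210
GONAL-f,199F051,release_simulation,z_number,190
GONAL-f,199F051,release_simulation,a_index,253
Bemfola,PPS30403,alpha_Asn52,z_number,216
Bemfola,PPS30403,alpha_Asn52,a_index,251
Bemfola,PPS30403,alpha_Asn78,z_number,180
Bemfola,PPS30403,alpha_Asn78,a_index,232
Bemfola,PPS30403,beta_Asn7,z_number,246
Bemfola,PPS30403,beta_Asn7,a_index,418
Bemfola,PPS30403,beta_Asn24,z_number,198
Bemfola,PPS30403,beta_Asn24,a_index,240
Bemfola,PPS30403,release_simulation,z_number,210
Bemfola,PPS30403,release_simulation,a_index,285
Bemfola,PNS30226,alpha_Asn52,z_number,217
Bemfola,PNS30226,alpha_Asn52,a_index,253
Bemfola,PNS30226,alpha_Asn78,z_number,180
Bemfola,PNS30226,alpha_Asn78,a_index,232
Bemfola,PNS30226,beta_Asn7,z_number,249
Bemfola,PNS30226,beta_Asn7,a_index,423
Bemfola,PNS30226,beta_Asn24,z_number,197
Bemfola,PNS30226,beta_Asn24,a_index,238
Bemfola,PNS30226,release_simulation,z_number,211
Bemfola,PNS30226,release_simulation,a_index,287
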