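attribute,agreement,partial,disagreement
Latitude/longitude,73,5,2
Ecosystem type,56,14,10
Monitoring start date,48,16,16
Monitoring end date,49,13,18
Restoration start date,45,16,19
Response variables,21,58,1
Restoration actions,32,36,12
Focal species,27,39,14
Study site,25,37,18
Sampling/monitoring methods,19,43,18
Restoration end date,35,10,35
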