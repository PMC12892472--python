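attribute,TP,FP,FN,TN
Latitude/longitude,86,18,0,29
Monitoring end date,63,15,8,4
Monitoring start date,59,23,14,1
Restoration start date,67,36,15,6
Response variables,414,304,828,0
Study site,163,133,496,0
Ecosystem type,124,123,94,0
Restoration actions,174,205,354,1
Sampling/monitoring methods,209,271,664,0
Focal species,225,299,332,4
Restoration end date,23,39,12,23
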