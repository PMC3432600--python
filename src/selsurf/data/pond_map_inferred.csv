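collection,unique_pond
AZ0602,AZ-02
AZ0603,AZ-03
AZ0604,AZ-04
AZ0605,AZ-05
AZ0606,AZ-06
AZ0607,AZ-07
NM0608,NM-08
AZ0710,AZ-10
AZ0711,AZ-11
AZ0706,AZ-06
AZ0801,AZ-01
AZ0810,AZ-10
AZ0811,AZ-11
AZ0816,AZ-16
AZ0809,AZ-09
AZ0802,AZ-02
AZ0812,AZ-12
AZ0813,AZ-13
NM0810,NM-10
AZ0903,AZ-03
AZ0902,AZ-02
AZ0904,AZ-04
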