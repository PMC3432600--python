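pond,map_id,year,n,tadpole_density,shrimp_density,cover
AZ0602,1,2006,93,2,3,0.8
AZ0603,2,2006,124,1,2,0.75
AZ0604,3,2006,50,2,3,0.5
AZ0605,4,2006,176,3,2,0.6
AZ0606,5,2006,94,2,1,0.9
AZ0607,6,2006,102,2,1,0.4
NM0608,7,2006,165,3,2,1
AZ0710,8,2007,78,3,1,0.9
AZ0711,9,2007,99,2,3,1
AZ0706,10,2007,125,1,2,0.7
AZ0801,11,2008,99,1,2,1
AZ0810,12,2008,213,3,2,0.8
AZ0811,13,2008,181,3,3,0.5
AZ0816,14,2008,297,3,2,1
AZ0809,15,2008,59,3,3,1
AZ0802,16,2008,150,2,2,0.7
AZ0812,17,2008,188,2,2,0.6
AZ0813,18,2008,135,2,2,1
NM0810,19,2008,169,2,2,0.8
AZ0903,20,2009,78,3,1,0.75
AZ0902,21,2009,211,3,3,1
AZ0904,22,2009,192,1,1,1
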