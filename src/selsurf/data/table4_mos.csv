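pond,map_id,F_min,p_min,p_min_is_bound,F_max,p_max,p_max_is_bound,fitness_extremum
AZ0604,3,5.124,0.028,False,10.522,0.002,False,Y
AZ0605,4,48.257,0.0001,True,80.282,0.0001,True,Y
AZ0607,6,12.177,0.0007,False,5.311,0.024,False,Y
NM0608,7,7.810,0.005,False,16.573,0.0001,True,Y
AZ0710,8,12.492,0.0006,False,30.103,0.0001,True,Y
AZ0711,9,28.468,0.0001,True,1.559,0.214,False,N
AZ0801,11,31.686,0.0001,True,8.232,0.005,False,Y
AZ0810,12,23.971,0.0001,True,61.126,0.0001,True,Y
AZ0811,13,21.384,0.0001,True,38.224,0.0001,True,Y
AZ0816,14,85.242,0.0001,True,172.109,0.0001,True,Y
AZ0802,16,24.155,0.0001,True,10.773,0.001,False,Y
AZ0812,17,20.838,0.0001,True,36.537,0.0001,True,Y
AZ0813,18,5.154,0.024,False,14.562,0.0002,False,Y
NM0810,19,10.912,0.001,False,16.500,0.0001,True,Y
AZ0903,20,0.083,0.773,False,0.317,0.574,False,N
AZ0902,21,1.691,0.194,False,14.560,0.0001,False,N
AZ0904,22,39.010,0.0001,True,9.252,0.002,False,Y
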