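pond,map_id,year,beta,se_beta,t_beta,p_beta,p_beta_is_bound,gamma,se_gamma,t_gamma,p_gamma,p_gamma_is_bound
AZ0602,1,2006,0.022,0.006,3.678,0.0003,False,0.013,0.012,1.181,0.240,False
AZ0603,2,2006,0.020,0.005,3.667,0.0003,False,0.019,0.011,1.639,0.103,False
AZ0604,3,2006,0.014,0.008,1.622,0.111,False,0.039,0.013,2.874,0.006,False
AZ0605,4,2006,0.031,0.009,3.487,0.0006,False,0.126,0.014,8.258,0.0001,True
AZ0606,5,2006,0.003,0.002,1.423,0.159,False,-0.001,0.004,-0.170,0.866,False
AZ0607,6,2006,-0.017,0.007,-2.354,0.020,False,0.038,0.012,2.920,0.004,False
NM0608,7,2006,0.009,0.004,2.253,0.025,False,0.024,0.006,3.596,0.0004,False
AZ0710,8,2007,0.026,0.006,3.857,0.0002,False,0.043,0.008,4.552,0.0001,True
AZ0711,9,2007,0.076,0.009,8.262,0.0001,True,-0.060,0.018,-3.113,0.002,False
AZ0706,10,2007,0.006,0.003,1.670,0.097,False,0.005,0.005,0.936,0.351,False
AZ0801,11,2008,0.030,0.006,4.417,0.0001,True,-0.036,0.008,-4.618,0.0001,True
AZ0810,12,2008,0.042,0.006,6.841,0.0001,True,0.075,0.012,6.467,0.0001,True
AZ0811,13,2008,0.008,0.003,2.318,0.021,False,0.024,0.004,5.741,0.0001,True
AZ0816,14,2008,0.029,0.004,6.781,0.0001,True,0.068,0.006,11.412,0.0001,True
AZ0809,15,2008,0.017,0.006,2.796,0.007,True,0.009,0.008,1.224,0.226,False
AZ0802,16,2008,0.005,0.001,2.714,0.007,False,0.011,0.002,4.377,0.0001,True
AZ0812,17,2008,0.009,0.003,2.699,0.007,False,0.029,0.006,5.557,0.0001,True
AZ0813,18,2008,0.017,0.005,3.095,0.002,False,0.028,0.010,3.110,0.002,False
NM0810,19,2008,0.006,0.004,1.518,0.131,False,0.033,0.008,3.812,0.0001,False
AZ0903,20,2009,0.020,0.012,1.638,0.105,False,0.001,0.020,0.089,0.929,False
AZ0902,21,2009,0.017,0.002,6.017,0.0001,True,0.016,0.006,2.692,0.007,False
AZ0904,22,2009,0.012,0.002,5.326,0.0001,True,-0.010,0.002,-4.917,0.0001,True
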