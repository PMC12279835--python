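species,tissue,metal,mean_ug_per_kg,sd_ug_per_kg,n
Nemipterus japonicus,liver,As,0.034,0.004,6
Nemipterus japonicus,liver,Cd,0.731,0.035,6
Nemipterus japonicus,liver,Cr,5.846,1.292,6
Nemipterus japonicus,liver,Hg,0.020,0.004,6
Nemipterus japonicus,liver,Pb,15.829,0.854,6
Nemipterus japonicus,liver,Sr,1.195,0.641,6
Nemipterus japonicus,liver,V,0.314,0.234,6
Nemipterus japonicus,gills,As,0.096,0.102,6
Nemipterus japonicus,gills,Cd,0.697,0.008,6
Nemipterus japonicus,gills,Cr,5.284,1.283,6
Nemipterus japonicus,gills,Hg,0.021,0.004,6
Nemipterus japonicus,gills,Pb,15.400,0.415,6
Nemipterus japonicus,gills,Sr,2.430,2.488,6
Nemipterus japonicus,gills,V,0.157,0.018,6
Nemipterus japonicus,muscle,As,0.308,0.083,6
Nemipterus japonicus,muscle,Cd,0.698,0.015,6
Nemipterus japonicus,muscle,Cr,6.611,0.661,6
Nemipterus japonicus,muscle,Hg,0.027,0.004,6
Nemipterus japonicus,muscle,Pb,15.524,0.087,6
Nemipterus japonicus,muscle,Sr,3.711,0.955,6
Nemipterus japonicus,muscle,V,0.169,0.007,6
Oreochromis mossambicus,liver,As,0.121,0.010,6
Oreochromis mossambicus,liver,Cd,0.731,0.031,6
Oreochromis mossambicus,liver,Cr,8.388,0.250,6
Oreochromis mossambicus,liver,Hg,0.050,0.010,6
Oreochromis mossambicus,liver,Pb,16.766,0.718,6
Oreochromis mossambicus,liver,Sr,14.135,0.839,6
Oreochromis mossambicus,liver,V,0.482,0.016,6
Oreochromis mossambicus,gills,As,0.091,0.026,6
Oreochromis mossambicus,gills,Cd,0.778,0.075,6
Oreochromis mossambicus,gills,Cr,6.831,1.501,6
Oreochromis mossambicus,gills,Hg,0.066,0.060,6
Oreochromis mossambicus,gills,Pb,16.894,1.467,6
Oreochromis mossambicus,gills,Sr,3.302,1.324,6
Oreochromis mossambicus,gills,V,0.484,0.251,6
Oreochromis mossambicus,muscle,As,0.218,0.218,6
Oreochromis mossambicus,muscle,Cd,0.748,0.066,6
Oreochromis mossambicus,muscle,Cr,12.399,5.384,6
Oreochromis mossambicus,muscle,Hg,0.048,0.040,6
Oreochromis mossambicus,muscle,Pb,17.649,1.802,6
Oreochromis mossambicus,muscle,Sr,9.623,3.496,6
Oreochromis mossambicus,muscle,V,1.208,1.371,6
Lates niloticus,liver,As,0.443,0.079,6
Lates niloticus,liver,Cd,0.777,0.021,6
Lates niloticus,liver,Cr,8.330,0.792,6
Lates niloticus,liver,Hg,0.031,0.005,6
Lates niloticus,liver,Pb,17.250,0.698,6
Lates niloticus,liver,Sr,3.199,0.870,6
Lates niloticus,liver,V,0.227,0.022,6
Lates niloticus,gills,As,0.315,0.252,6
Lates niloticus,gills,Cd,0.718,0.025,6
Lates niloticus,gills,Cr,7.114,1.300,6
Lates niloticus,gills,Hg,0.038,0.015,6
Lates niloticus,gills,Pb,15.912,0.560,6
Lates niloticus,gills,Sr,15.200,12.859,6
Lates niloticus,gills,V,0.318,0.142,6
Lates niloticus,muscle,As,0.141,0.202,6
Lates niloticus,muscle,Cd,0.696,0.009,6
Lates niloticus,muscle,Cr,5.259,1.682,6
Lates niloticus,muscle,Hg,0.024,0.002,6
Lates niloticus,muscle,Pb,15.364,0.155,6
Lates niloticus,muscle,Sr,1.068,0.843,6
Lates niloticus,muscle,V,0.150,0.024,6
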