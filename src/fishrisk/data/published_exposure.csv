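species,metal,cohort,edi,ewi,dil,crlim
Nemipterus japonicus,As,children,1.155,8.085,19.480,19.480
Nemipterus japonicus,As,adults,0.660,4.620,68.181,68.181
Nemipterus japonicus,Cd,children,2.617,18.3225,28.653,28.653
Nemipterus japonicus,Cd,adults,1.495,10.470,100.286,100.286
Nemipterus japonicus,Cr,children,24.791,173.538,4537.891,4537.891
Nemipterus japonicus,Cr,adults,14.166,99.165,15882.619,15882.619
Nemipterus japonicus,Hg,children,0.101,0.708,74.074,74.074
Nemipterus japonicus,Hg,adults,0.057,0.405,259.259,259.259
Nemipterus japonicus,Pb,children,58.215,407.505,0.386,0.386
Nemipterus japonicus,Pb,adults,33.265,232.860,1.352,1.352
Nemipterus japonicus,Sr,children,13.916,97.413,18.862,18.862
Nemipterus japonicus,Sr,adults,7.952,55.665,66.019,66.019
Nemipterus japonicus,V,children,0.633,4.436,1065.088,1065.088
Nemipterus japonicus,V,adults,0.362,2.535,3727.810,3727.810
Oreochromis mossambicus,As,children,0.817,5.722,27.522,27.522
Oreochromis mossambicus,As,adults,0.467,3.270,96.330,96.330
Oreochromis mossambicus,Cd,children,2.805,19.635,26.737,26.737
Oreochromis mossambicus,Cd,adults,1.602,11.220,93.582,93.582
Oreochromis mossambicus,Cr,children,46.496,325.473,2419.549,2419.549
Oreochromis mossambicus,Cr,adults,26.569,185.985,8468.424,8468.424
Oreochromis mossambicus,Hg,children,0.180,1.260,41.666,41.666
Oreochromis mossambicus,Hg,adults,0.102,0.720,145.833,145.833
Oreochromis mossambicus,Pb,children,66.183,463.2862,0.339,0.339
Oreochromis mossambicus,Pb,adults,37.819,264.735,1.189,1.18
Oreochromis mossambicus,Sr,children,36.086,252.603,7.274,7.274
Oreochromis mossambicus,Sr,adults,20.620,144.345,25.459,25.459
Oreochromis mossambicus,V,children,4.530,31.701,149.006,149.006
Oreochromis mossambicus,V,adults,2.588,18.120,521.523,521.523
Lates niloticus,As,children,0.528,3.701,42.553,42.553
Lates niloticus,As,adults,0.302,2.115,148.936,148.936
Lates niloticus,Cd,children,2.610,18.270,28.735,28.735
Lates niloticus,Cd,adults,1.491,10.440,100.574,100.574
Lates niloticus,Cr,children,19.721,138.048,5704.506,5704.506
Lates niloticus,Cr,adults,11.269,78.885,19965.772960,19965.772
Lates niloticus,Hg,children,0.090,0.630,83.333,83.3333
Lates niloticus,Hg,adults,0.051,0.360,291.666,291.666
Lates niloticus,Pb,children,57.615,403.305,0.390,0.390
Lates niloticus,Pb,adults,32.922,230.460,1.366,1.366
Lates niloticus,Sr,children,4.005,28.035,65.543,65.543
Lates niloticus,Sr,adults,2.288,16.020,229.400,229.400
Lates niloticus,V,children,0.562,3.937,1200.000,1200.000
Lates niloticus,V,adults,0.321,2.250,4200.000,4200.000
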