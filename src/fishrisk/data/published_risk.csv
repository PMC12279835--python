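species,metal,cohort,thq,cr
Nemipterus japonicus,As,children,0.003,1.73e-6
Nemipterus japonicus,As,adults,0.002,9.90e-7
Nemipterus japonicus,Cd,children,0.002,1.31e-10
Nemipterus japonicus,Cd,adults,0.001,7.47e-11
Nemipterus japonicus,Cr,children,0.000,1.02e-6
Nemipterus japonicus,Cr,adults,0.000,5.82e-7
Nemipterus japonicus,Hg,children,0.001,
Nemipterus japonicus,Hg,adults,0.001,
Nemipterus japonicus,Pb,children,0.194,4.95e-7
Nemipterus japonicus,Pb,adults,0.110,2.83e-7
Nemipterus japonicus,Sr,children,0.004,
Nemipterus japonicus,Sr,adults,0.002,
Nemipterus japonicus,V,children,0.000,
Nemipterus japonicus,V,adults,0.000,
Oreochromis mossambicus,As,children,0.003,1.23e-6
Oreochromis mossambicus,As,adults,0.002,7.01e-7
Oreochromis mossambicus,Cd,children,0.003,1.40e-10
Oreochromis mossambicus,Cd,adults,0.002,8.01e-11
Oreochromis mossambicus,Cr,children,0.000,1.91e-6
Oreochromis mossambicus,Cr,adults,0.000,1.09e-6
Oreochromis mossambicus,Hg,children,0.002,
Oreochromis mossambicus,Hg,adults,0.001,
Oreochromis mossambicus,Pb,children,0.221,5.63e-7
Oreochromis mossambicus,Pb,adults,0.126,3.21e-7
Oreochromis mossambicus,Sr,children,0.010,
Oreochromis mossambicus,Sr,adults,0.006,
Oreochromis mossambicus,V,children,0.001,
Oreochromis mossambicus,V,adults,0.000,
Lates niloticus,As,children,0.002,7.93e-7
Lates niloticus,As,adults,0.001,4.53e-7
Lates niloticus,Cd,children,0.003,1.31e-10
Lates niloticus,Cd,adults,0.001,7.40e-11
Lates niloticus,Cr,children,0.000,8.08e-7
Lates niloticus,Cr,adults,0.000,4.62e-7
Lates niloticus,Hg,children,0.001,
Lates niloticus,Hg,adults,0.001,
Lates niloticus,Pb,children,0.192,4.91e-7
Lates niloticus,Pb,adults,0.109,2.81e-7
Lates niloticus,Sr,children,0.001,
Lates niloticus,Sr,adults,0.001,
Lates niloticus,V,children,0.000,
Lates niloticus,V,adults,0.000,
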