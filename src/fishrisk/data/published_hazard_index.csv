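species,cohort,hi
Nemipterus japonicus,children,0.205
Nemipterus japonicus,adults,0.117
Oreochromis mossambicus,children,0.239
Oreochromis mossambicus,adults,0.136
Lates niloticus,children,0.198
Lates niloticus,adults,0.113
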