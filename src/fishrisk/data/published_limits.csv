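metal,cohort,mdi,mwi
As,children,42.857,300
As,adults,150.000,1050
Cd,children,20.000,140
Cd,adults,70.000,490
Cr,children,71.429,500
Cr,adults,250.000,1750
Hg,children,11.429,80
Hg,adults,40.000,280
Pb,children,71.429,500
Pb,adults,250.000,1750
Sr,children,20000.000,140000
Sr,adults,70000.000,490000
V,children,20.000,140
V,adults,70.000,490
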