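# Toxicological reference values used by the risk pipeline.
#
# Units:
#   rfd  — oral reference dose, ug per kg body weight per day
#   ptwi — provisional tolerable weekly intake, ug per kg body weight per week
#   csf  — oral cancer slope factor, (mg per kg body weight per day)^-1
#
# Each value carries a provenance flag:
#   "paper-stated" — printed in the source study report
#   "back-derived" — recovered by inverting the study's published output
#                    tables (DIL -> RfD, MDI -> PTWI, CR -> CSF)
#   "user"         — supplied by the user at run time
#
# A metal with no csf entry has no oral slope factor (Hg, Sr, V render
# as "-" in cancer-risk reports and are excluded from CR aggregates).
# These defaults are deliberately replaceable: pass --refs to the CLI or
# ReferenceValueSet.from_toml() to substitute agency values of your choice.

schema = 1

[As]
rfd = 0.3
rfd_provenance = "back-derived"
ptwi = 15.0
ptwi_provenance = "paper-stated"
csf = 1.5
csf_provenance = "back-derived"

[Cd]
rfd = 1.0
rfd_provenance = "back-derived"
ptwi = 7.0
ptwi_provenance = "paper-stated"
csf = 5.0e-5
csf_provenance = "back-derived"

[Cr]
rfd = 1500.0
rfd_provenance = "back-derived"
ptwi = 25.0
ptwi_provenance = "back-derived"
csf = 0.041
csf_provenance = "back-derived"

[Hg]
rfd = 0.1
rfd_provenance = "back-derived"
ptwi = 4.0
ptwi_provenance = "paper-stated"

[Pb]
rfd = 0.3
rfd_provenance = "back-derived"
ptwi = 25.0
ptwi_provenance = "paper-stated"
csf = 0.0085
csf_provenance = "back-derived"

[Sr]
rfd = 3.5
rfd_provenance = "back-derived"
ptwi = 7000.0
ptwi_provenance = "back-derived"

[V]
rfd = 9.0
rfd_provenance = "back-derived"
ptwi = 7.0
ptwi_provenance = "back-derived"
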