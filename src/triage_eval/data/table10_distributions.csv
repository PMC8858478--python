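# AIS grade distributions (percent) reported by four published cohorts:
# motor-vehicle accidents (Baker et al., 1974), adult falls (Lopes et
# al., 2014), tornado injuries (Deng et al., 2018) and traumatic
# maternal injuries (Awoleke et al., 2019).  "printed" rows are the
# values as published (several do not sum to 100 and are renormalised
# at load time).  The "corrected" Baker row reconciles the printed row
# with the same cohort's main-injury grade distribution (4/20/49/13/13%),
# reading its "42" as 4.2 and "4.92" as 49.2; it sums to 100 exactly
# and is a synthetic reconstruction, flagged by its variant name.
source,variant,ais1,ais2,ais3,ais4,ais5
baker,printed,42,20.2,4.92,13.2,13.2
baker,corrected,4.2,20.2,49.2,13.2,13.2
lopes,printed,36.57,29.73,27.81,3.54,2.32
deng,printed,60.85,15.46,14.46,6.73,17.5
awoleke,printed,40.06,48.6,8.30,25,0
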