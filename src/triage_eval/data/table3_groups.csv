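# Mortality by the AIS grades of the three most severe injuries in the
# 1974 cohort: three person-count groups (102 / 78 / 38), each split by
# whether the third-worst injury C is below 3 or equal to 3.
n_persons,A,B,C,percent_died
102,4,3,0-2,18
102,4,3,3,43
78,5,3,0-2,59
78,5,3,3,86
38,5,4,0-2,62
38,5,4,3,92
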