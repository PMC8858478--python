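# Distribution of the AIS grade of the main injury over the 2,128
# motor-vehicle-accident victims of the 1968-69 Baltimore cohort
# (Baker et al., 1974).  Percentages as printed; 1% "unknown" omitted,
# so the loader renormalises over grades 1..5.
grade,percent
1,4
2,20
3,49
4,13
5,13
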