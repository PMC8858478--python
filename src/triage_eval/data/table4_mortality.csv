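# Mortality rate (percent) per AIS profile for the 2,128 patients of the
# 1974 cohort; the table that originally motivated the sum-of-squares
# aggregation.  Columns A,B,C are the three highest AIS grades.
A,B,C,outcome
4,3,0,18
4,3,1,18
4,3,2,18
4,3,3,43
5,3,0,59
5,3,1,59
5,3,2,59
5,3,3,86
5,4,0,62
5,4,1,62
5,4,2,62
5,4,3,92
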