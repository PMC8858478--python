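# Published reference mean waiting times (time-units; one unit = one mean
# service time) for the overloaded M/M/1 priority queue: lambda=10, mu=1,
# 100 replications of 1000 time-units, priority = sum / sum of squares /
# sum of cubes of the three highest AIS grades.  Empty cells: the Awoleke
# distribution has no grade-5 mass, hence no critical patients.
source,wait_all_sum,wait_all_iss,wait_all_cubes,wait_critical_sum,wait_critical_iss,wait_critical_cubes
baker,71.48,39.14,38.49,71.47,39.12,38.45
lopes,61.11,41.58,40.31,61.80,42.03,39.17
deng,72.56,42.71,42.42,58.89,42.39,42.15
awoleke,134.90,91.93,91.93,,,
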