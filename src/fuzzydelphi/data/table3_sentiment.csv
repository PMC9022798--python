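factor,negative_score,positive_score,sentiment
Capacity,0.021,0.010,Negative
Temporal,0.027,0.007,Negative
Quality,0.007,0.010,Positive
Outcomes,0.006,0.005,Negative
Financial expenditures,0.007,0.008,Positive
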