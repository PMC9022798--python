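factor,indicator_id,fdm_avg_fuzzy,fdm_consensus,mofd_avg_fuzzy,mofd_consensus
Capacity,ed_beds,0.128,95.556,0.113,77.879
Capacity,icu_beds,0.152,91.111,0.167,75.063
Capacity,physician_staffing,0.33,35.556,0.307,49.958
Capacity,midlevel_provider_staffing,0.348,46.667,0.328,50.148
Capacity,nurse_staffing,0.218,86.667,0.167,62.184
Capacity,patient_acuity_level,0.546,51.111,0.586,47.281
Capacity,physician_staffing_per_patient_seen,0.594,44.444,0.647,47.618
Capacity,nurse_staffing_per_patient_seen,0.647,80.0,0.709,52.943
Capacity,backup_physician,0.486,62.222,0.464,48.229
Capacity,backup_nurse,0.549,57.778,0.56,45.711
Capacity,patient_care_compromised,0.628,80.0,0.668,51.371
Capacity,medical_support_personnel,0.353,40.0,0.322,48.941
Temporal,high_acuity,0.377,37.778,0.35,45.114
Temporal,low_acuity,0.168,86.667,0.126,69.32
Temporal,admit_ed_los,0.139,88.889,0.099,75.033
Temporal,discharge_ed_los,0.153,86.667,0.129,72.361
Temporal,time_to_triage,0.353,62.222,0.334,53.917
Temporal,time_to_start_of_treatment,0.319,53.333,0.288,52.762
Temporal,time_to_ed_bed,0.324,48.889,0.283,50.826
Temporal,time_to_treatment_condition,0.299,66.667,0.268,57.95
Quality,employee_fatigue,0.724,100.0,0.741,60.947
Quality,employee_satisfaction,0.14,91.111,0.119,75.279
Quality,medical_errors,0.597,64.444,0.602,52.572
Outcomes,patients_hospitalized,0.458,93.333,0.454,64.093
Outcomes,patient_transfers,0.353,35.556,0.322,49.14
Financial expenditures,increase_diagnostic_test,0.538,64.444,0.54,49.038
Financial expenditures,increase_ed_treatment,0.476,48.889,0.46,44.28
Financial expenditures,increase_ed_revenue,0.387,68.889,0.385,61.557
Financial expenditures,increase_in_non_labor_cost,0.564,66.667,0.571,51.65
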