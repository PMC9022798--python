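factor,indicator_id,fdm_avg_fuzzy,fdm_consensus,mofd_avg_fuzzy,mofd_consensus
Capacity,physician_staffing,0.478,52.174,0.473,51.15
Capacity,midlevel_provider_staffing,0.557,69.565,0.571,57.06
Capacity,patient_acuity_level,0.643,86.957,0.691,56.91
Capacity,physician_staffing_per_patient_seen,0.661,91.304,0.665,63.41
Capacity,nurse_staffing_per_patient_seen,,,0.781,77.34
Capacity,backup_physician,0.452,69.565,0.434,54.08
Capacity,backup_nurse,0.576,60.87,0.585,49.23
Capacity,patient_care_compromised,,,0.702,56.7
Capacity,medical_support_personnel,0.557,52.174,0.567,45.87
Temporal,high_acuity,0.557,60.87,0.582,48.2
Temporal,time_to_start_of_treatment,0.43,78.261,0.43,57.02
Temporal,time_to_ed_bed,0.443,56.522,0.44,43.53
Quality,medical_errors,,,0.618,52.25
Outcomes,patient_transfers,0.239,91.304,0.205,65.64
Financial expenditures,increase_diagnostic_test,,,0.546,52.51
Financial expenditures,increase_ed_treatment,0.522,78.261,0.537,58.27
Financial expenditures,increase_in_non_labor_cost,,,0.579,55.82
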