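rank,normal_conditions,surge_conditions
1,increase_in_non_labor_cost,ed_beds
2,increase_ed_revenue,nurse_staffing_per_patient_seen
3,patients_hospitalized,employee_satisfaction
4,time_to_start_of_treatment,icu_beds
5,medical_errors,admit_ed_los
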