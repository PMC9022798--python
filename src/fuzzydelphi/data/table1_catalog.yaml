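# Default catalog: 29 emergency-department performance indicators in 5
# healthcare performance factors (Capacity, Temporal, Quality, Outcomes,
# Financial expenditures).
factors:
  Capacity:
    - {id: ed_beds, name: "ED beds"}
    - {id: icu_beds, name: "ICU beds"}
    - {id: physician_staffing, name: "Physician staffing"}
    - {id: midlevel_provider_staffing, name: "Midlevel provider staffing"}
    - {id: nurse_staffing, name: "Nurse staffing"}
    - {id: patient_acuity_level, name: "Patient acuity level"}
    - {id: physician_staffing_per_patient_seen, name: "Physician staffing per patient seen"}
    - {id: nurse_staffing_per_patient_seen, name: "Nurse staffing per patient seen"}
    - {id: backup_physician, name: "Backup physician"}
    - {id: backup_nurse, name: "Backup nurse"}
    - {id: patient_care_compromised, name: "Patient care compromised"}
    - {id: medical_support_personnel, name: "Medical support personnel"}
  Temporal:
    - {id: high_acuity, name: "High acuity"}
    - {id: low_acuity, name: "Low acuity"}
    - {id: admit_ed_los, name: "Admit ED LOS < 6 hours"}
    - {id: discharge_ed_los, name: "Discharge ED LOS < 4 hours"}
    - {id: time_to_triage, name: "Time to triage"}
    - {id: time_to_start_of_treatment, name: "Time to start of treatment"}
    - {id: time_to_ed_bed, name: "Time to ED bed"}
    - {id: time_to_treatment_condition, name: "Time to treatment condition"}
  Quality:
    - {id: employee_fatigue, name: "Employee fatigue"}
    - {id: employee_satisfaction, name: "Employee satisfaction"}
    - {id: medical_errors, name: "Medical errors"}
  Outcomes:
    - {id: patients_hospitalized, name: "Patients hospitalized"}
    - {id: patient_transfers, name: "Patient transfers"}
  Financial expenditures:
    - {id: increase_diagnostic_test, name: "Increase diagnostic test"}
    - {id: increase_ed_treatment, name: "Increase ED treatment"}
    - {id: increase_ed_revenue, name: "Increase ED revenue"}
    - {id: increase_in_non_labor_cost, name: "Increase in non-labor cost"}
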