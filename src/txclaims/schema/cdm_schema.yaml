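# Common data model for regional claims bundles.
# Semantic types: identifier | date (claims-window checked) | date_any
# (historical, not window checked) | code:<SYSTEM> | quantity | text.
# No direct identifiers (name, fiscal code) exist anywhere in the model;
# tables link through the anonymous person identifier only.
version: 1
claims_window:
  start: 2005-01-01
  end: 2019-12-31
code_systems:
  ICD9_PROC: '^\d{2}\.\d{1,2}$'
  ICD9_DX: '^[V\d]\d{1,2}(\.\d{1,2})?$'
  ATC: '^[A-Z]\d{2}[A-Z]{2}\d{2}$'
  AIC: '^[A-Z]\d{8}$'
  DRG: '^\w+$'
tables:
  hospital_discharge:
    required: true
    fields:
      person_id: identifier
      admission_date: date
      discharge_date: date
      hospital_code: text
      drg_code: code:DRG
      dx_1: code:ICD9_DX
      dx_2: code:ICD9_DX
      dx_3: code:ICD9_DX
      dx_4: code:ICD9_DX
      dx_5: code:ICD9_DX
      dx_6: code:ICD9_DX
      proc_1: code:ICD9_PROC
      proc_2: code:ICD9_PROC
      proc_3: code:ICD9_PROC
      proc_4: code:ICD9_PROC
      proc_5: code:ICD9_PROC
      proc_6: code:ICD9_PROC
  drug_dispensing:
    required: true
    fields:
      person_id: identifier
      dispensing_date: date
      atc_code: code:ATC
      aic_code: code:AIC
      n_packages: quantity
      cost_euro: quantity
  inhabitant_registry:
    required: true
    fields:
      person_id: identifier
      sex: text
      birth_date: date_any
      registration_start: date_any
      registration_end: date_any
  mortality_registry:
    required: true
    fields:
      person_id: identifier
      death_date: date
      cause_code: code:ICD9_DX
  emergency_visits:
    required: false
    fields:
      person_id: identifier
      admission_date: date
      discharge_date: date
      reason_code: code:ICD9_DX
  exemptions:
    required: false
    fields:
      person_id: identifier
      exemption_code: text
      start_date: date
  outpatient_tests:
    required: false
    fields:
      person_id: identifier
      test_date: date
      test_code: text
      lab_code: text
# Event-level analytical dataset: the minimal fields the study reads.
analytical:
  relevant_atc_prefixes: [L04, H02AB, B01AA, B01AC, C10AA, J01]
  tables:
    persons: [pid, region, sex, birth_date]
    hospitalizations: [pid, region, admission_date, discharge_date,
                       hospital_code, dx_1, dx_2, dx_3, dx_4, dx_5, dx_6,
                       proc_1, proc_2, proc_3, proc_4, proc_5, proc_6]
    dispensings: [pid, region, dispensing_date, atc_code, aic_code, n_packages]
    deaths: [pid, region, death_date]
    registration: [pid, region, registration_start, registration_end]
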