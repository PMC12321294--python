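# Default flattening map for Beacon v2 `individuals` records.
# Column set reconstructed from the public Beacon default model at the depth
# the bundled mock cohorts populate; adjust freely for other beacons.
entity: individuals
columns:
  - name: individual_id
    path: id
  - name: sex_id
    path: sex.id
  - name: sex_label
    path: sex.label
  - name: vital_status
    path: vitalStatus.label
  - name: followup_time_days
    path: followupTime
  - name: disease_codes
    path: diseases[].diseaseCode.id
    cardinality: join
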