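# Default flattening map for Beacon v2 `biosamples` records.
entity: biosamples
columns:
  - name: biosample_id
    path: id
  - name: individual_id
    path: individualId
  - name: histological_diagnosis_id
    path: histologicalDiagnosis.id
  - name: histological_diagnosis_label
    path: histologicalDiagnosis.label
  - name: biosample_status
    path: biosampleStatus.label
  - name: external_references
    path: externalReferences[].id
    cardinality: join
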