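# Default flattening map for Beacon v2 `analyses` records.
entity: analyses
columns:
  - name: analysis_id
    path: id
  - name: biosample_id
    path: biosampleId
  - name: individual_id
    path: individualId
  - name: platform
    path: platformModel.label
  - name: pipeline
    path: pipelineName
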