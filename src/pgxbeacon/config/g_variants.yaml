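# Default flattening map for Beacon v2 `g_variants` records (CNV-flavoured:
# one record per copy-number call with interbase coordinates and a log2 ratio).
entity: g_variants
columns:
  - name: variant_id
    path: id
  - name: analysis_id
    path: analysisId
  - name: biosample_id
    path: biosampleId
  - name: chromosome
    path: referenceName
  - name: start
    path: start
  - name: end
    path: end
  - name: variant_state
    path: variantState.id
  - name: log2
    path: log2
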