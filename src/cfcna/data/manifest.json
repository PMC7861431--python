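{
  "table3_targeted.tsv": {"rows": 23, "units": {"ratio_pct": "percent"}},
  "table2_patient_summary.tsv": {"rows": 44,
                                 "units": {"ctdna_fraction_pct": "percent"}}
}
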