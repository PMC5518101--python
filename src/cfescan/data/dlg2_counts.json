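{
  "gddid": {
    "comment": "GDD/ID validation cohorts: deletions in the DLG2 7-9 region affecting either HP region. Results-text counts (they reproduce the printed p value); the per-HP table alternatively lists control counts 4 and 1 of 19 - that discrepancy is carried here, not resolved.",
    "case_hp": 11,
    "case_total": 14,
    "control_hp": 3,
    "control_total": 19,
    "case_hpin7": 7,
    "case_hpin8": 4,
    "control_hpin7_text": 2,
    "control_hpin8_text": 1,
    "control_hpin7_table": 4,
    "control_hpin8_table": 1
  },
  "reference_values": {
    "hpin7_deletions": 15,
    "hpin8_deletions": 16,
    "either_hp_deletions": 26,
    "both_hp_deletions": 5,
    "n_patients": 29,
    "either_hp_percent": 90,
    "gddid_any_hp_p": 4.501e-4,
    "hpin8_entry_width": 2338
  }
}
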