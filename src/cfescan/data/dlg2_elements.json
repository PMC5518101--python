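{
  "build": "hg19",
  "gene": "DLG2",
  "strand": "-",
  "elements": {
    "HPin7": {"chrom": "chr11", "start": 84430074, "end": 84432618},
    "HPin8": {"chrom": "chr11", "start": 84147846, "end": 84149151},
    "CFEin7_coding": {"chrom": "chr11", "start": 84431339, "end": 84431401},
    "CFEin8_coding": {"chrom": "chr11", "start": 84148431, "end": 84148508}
  },
  "candidate_rows": {
    "HPin8_entry": {
      "chrom": "chr11", "start": 84147024, "end": 84149361, "width": 2338,
      "gene": "DLG2", "strand": "-", "n_cases": 15, "n_controls": 5,
      "splicing_site": "84148430-1", "type": "P", "enriched": true
    },
    "HPin7_entry": {
      "chrom": "chr11", "start": 84429842, "end": 84432885, "width": 3044,
      "gene": "DLG2", "strand": "-", "n_cases": 13, "n_controls": 2,
      "splicing_site": "84431338-9", "type": "N", "enriched": true
    }
  },
  "splice_boundaries": {
    "HPin7": {"pos": 84431338, "delta": 46, "context": "AGGT", "splices_into": "exon 8"},
    "HPin8": {"pos": 84148430, "delta": 59, "context": "AGGT", "splices_into": "exon 11"}
  }
}
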