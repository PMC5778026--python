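{
  "_comment": "Polymorphic-region coordinates for the two operon genes (group IV naming). Amino-acid intervals are 1-based inclusive; the nucleotide interval for aa [s,e] is [3s-2, 3e] in CDS frame. cidB carries an identically-duplicated 3' tail excluded from coverage from the given 1-based nt position to the gene end. cds_length_nt values are the synthetic gene-model lengths, chosen so every region and the tail exclusion fit; they are model parameters, not measured gene lengths.",
  "genes": {
    "cidA": {
      "group": "IV",
      "cds_length_nt": 1434,
      "regions": {
        "upstream": {"aa": [118, 152]},
        "downstream": {"aa": [336, 401]}
      },
      "upstream_labels": ["α", "β", "γ", "δ"],
      "downstream_labels": ["1", "2"]
    },
    "cidB": {
      "group": "IV",
      "cds_length_nt": 3249,
      "excluded_tail_start_nt": 2461,
      "regions": {
        "upstream": {"aa": [242, 278]},
        "downstream": {"aa": [450, 481]}
      },
      "upstream_labels": ["a", "b"],
      "downstream_labels": ["1", "2", "3"]
    }
  }
}
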