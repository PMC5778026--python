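{
  "_comment": "Restriction enzymes used by the shipped diagnostic tests. recognition is IUPAC; cut_offset is the number of bases after the recognition start, on the strand scanned. All four recognitions are degenerate-palindromic (revcomp(pattern) == pattern), so forward-strand scanning finds every site.",
  "enzymes": [
    {"name": "ApoI", "recognition": "RAATTY", "cut_offset": 1},
    {"name": "Hpy188I", "recognition": "TCNGA", "cut_offset": 3},
    {"name": "BanI", "recognition": "GGYRCC", "cut_offset": 1},
    {"name": "TaqI", "recognition": "TCGA", "cut_offset": 1}
  ]
}
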