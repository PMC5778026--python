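{
  "_comment": "Reference fragment patterns for the two diagnostic double digests. 'fragments' are the published band sizes in bp (descending). 'order' gives one positional arrangement of those fragments along the amplicon, and 'cut_enzymes' names the enzyme producing each internal cut boundary in that arrangement; these two fields let an amplicon with exactly this fragment map be constructed for validation. non_discriminating fragments are small bands not used to tell patterns apart. Note: one published source lists the beta/gamma second band as 123 bp, another as 122 bp; only 122 is consistent with the 778 bp amplicon total, so 122 ships as the default.",
  "tests": {
    "cidA_upstream": {
      "gene": "cidA",
      "amplicon_length": 778,
      "enzymes": ["ApoI", "Hpy188I"],
      "tolerance_bp": 5,
      "patterns": [
        {
          "name": "α",
          "fragments": [471, 122, 57, 53, 51, 24],
          "order": [471, 53, 122, 57, 51, 24],
          "cut_enzymes": ["ApoI", "Hpy188I", "ApoI", "Hpy188I", "Hpy188I"],
          "non_discriminating": [57, 53, 51, 24]
        },
        {
          "name": "β/γ",
          "fragments": [441, 122, 83, 57, 51, 24],
          "order": [441, 83, 122, 57, 51, 24],
          "cut_enzymes": ["Hpy188I", "Hpy188I", "ApoI", "Hpy188I", "Hpy188I"],
          "non_discriminating": [57, 51, 24]
        },
        {
          "name": "δ",
          "fragments": [524, 122, 57, 51, 24],
          "order": [524, 122, 57, 51, 24],
          "cut_enzymes": ["Hpy188I", "ApoI", "Hpy188I", "Hpy188I"],
          "non_discriminating": [57, 51, 24]
        }
      ]
    },
    "cidB_downstream": {
      "gene": "cidB",
      "amplicon_length": [1267, 1276],
      "enzymes": ["BanI", "TaqI"],
      "tolerance_bp": 5,
      "patterns": [
        {
          "name": "1",
          "amplicon_length": 1276,
          "fragments": [892, 239, 145],
          "order": [239, 892, 145],
          "cut_enzymes": ["TaqI", "BanI"],
          "non_discriminating": []
        },
        {
          "name": "2",
          "amplicon_length": 1267,
          "fragments": [1028, 239],
          "order": [239, 1028],
          "cut_enzymes": ["TaqI"],
          "non_discriminating": []
        },
        {
          "name": "3",
          "amplicon_length": 1267,
          "fragments": [861, 239, 167],
          "order": [239, 861, 167],
          "cut_enzymes": ["TaqI", "BanI"],
          "non_discriminating": []
        }
      ]
    }
  }
}
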