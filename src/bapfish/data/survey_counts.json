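{
  "comment": "Practice-survey counts: 54 clinical cytogenetics laboratories asked about their MYC rearrangement FISH strategy.",
  "items": [
    {"label": "MYC break-apart probe only at initial investigation", "k": 23, "n": 54},
    {"label": "MYC break-apart plus IGH/MYC dual-fusion at initial investigation", "k": 30, "n": 54},
    {"label": "MYC break-apart plus IGH-, IGK- and IGL-/MYC dual-fusion at initial investigation", "k": 1, "n": 54},
    {"label": "BCL2/BCL6 rearrangements sought upfront", "k": 36, "n": 54},
    {"label": "BCL2/BCL6 rearrangements queried only after a MYC rearrangement", "k": 14, "n": 54}
  ]
}
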