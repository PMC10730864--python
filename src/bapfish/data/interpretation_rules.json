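{
  "comment": "Decision table mapping a break-apart pattern class (plus confirmation status for unbalanced patterns) to a clinical-style interpretation. Editable: unbalanced-pattern branches key on whether a gene juxtaposition has been confirmed (true), excluded in favour of a pure copy-number change (false), or not yet investigated (unknown).",
  "fn_rate_caveat": "A normal break-apart result does not exclude a MYC rearrangement: break-apart testing alone carries a false-negative rate of at least 4%, reducible with IG/MYC dual-fusion probes.",
  "rules": {
    "NORMAL": {
      "category": "NEGATIVE_WITH_FN_CAVEAT",
      "narrative": "No isolated signals; fusion count matches ploidy. Negative for a MYC rearrangement by break-apart FISH, with the caveat that break-apart testing alone carries a false-negative rate of at least 4%.",
      "recommended_tests": ["IG/MYC D-FISH"]
    },
    "RGF": {
      "category": "POSITIVE_MYC_REARRANGEMENT",
      "narrative": "Balanced separation of red and green signals: the classic positive break-apart pattern of a MYC rearrangement.",
      "recommended_tests": []
    },
    "RF": {
      "unknown": {
        "category": "LIKELY_POSITIVE_RECOMMEND_TESTING",
        "narrative": "Isolated red signal(s) without isolated green: unbalanced pattern with relative gain of material 5' of MYC or loss of material 3' of MYC. Most such cases harbour a true structural variant juxtaposing MYC with a partner locus; an interpretation of 'likely positive' with confirmatory testing is recommended.",
        "recommended_tests": ["IG/MYC D-FISH", "MYC IHC", "WGS/RNAseq"]
      },
      "juxtaposition": {
        "category": "POSITIVE_MYC_REARRANGEMENT",
        "narrative": "Unbalanced red-fusion pattern with a confirmed structural variant juxtaposing MYC to a partner locus: positive for a MYC rearrangement.",
        "recommended_tests": []
      },
      "pure_cn": {
        "category": "CN_ALTERATION_NOT_CLASSIFIED_AS_R",
        "narrative": "Unbalanced red-fusion pattern explained by a copy-number alteration at the MYC locus without gene juxtaposition; not classified as a MYC rearrangement under current DLBCL/HGBCL schemes.",
        "recommended_tests": []
      }
    },
    "GF": {
      "unknown": {
        "category": "LIKELY_POSITIVE_RECOMMEND_TESTING",
        "narrative": "Isolated green signal(s) without isolated red: unbalanced pattern with relative gain of material 3' of MYC or loss of material 5' of MYC. An interpretation of 'likely positive' with confirmatory testing is recommended.",
        "recommended_tests": ["IG/MYC D-FISH", "MYC IHC", "WGS/RNAseq"]
      },
      "juxtaposition": {
        "category": "POSITIVE_MYC_REARRANGEMENT",
        "narrative": "Unbalanced green-fusion pattern with a confirmed structural variant juxtaposing MYC to a partner locus: positive for a MYC rearrangement.",
        "recommended_tests": []
      },
      "pure_cn": {
        "category": "CN_ALTERATION_NOT_CLASSIFIED_AS_R",
        "narrative": "Unbalanced green-fusion pattern explained by a copy-number alteration at the MYC locus without gene juxtaposition; not classified as a MYC rearrangement under current DLBCL/HGBCL schemes.",
        "recommended_tests": []
      }
    },
    "FUSION_CN": {
      "category": "CN_ALTERATION_NOT_CLASSIFIED_AS_R",
      "narrative": "Intact fusion signals at an abnormal copy number: copy-number change of the whole locus, not classified as a MYC rearrangement.",
      "recommended_tests": []
    },
    "AMBIGUOUS": {
      "category": "AMBIGUOUS_RECOMMEND_TESTING",
      "narrative": "The reported count ranges admit more than one pattern class; the result cannot be classified from nomenclature alone.",
      "recommended_tests": ["IG/MYC D-FISH", "MYC IHC", "WGS/RNAseq"]
    }
  }
}
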