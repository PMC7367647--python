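{
  "description": "Published per-category screening-count summaries from the liver-cancer plasma cfDNA study the default 29-segment panel derives from. Categories count significantly altered panel segments per sample at the Z cutoff 2.702; a sample is screen-positive with >=1 altered segment.",
  "category_labels": [">=3", "2", "1", "0"],
  "cohorts": {
    "discovery_control": {"label": "control", "counts": {">=3": 0, "2": 0, "1": 1, "0": 40}},
    "discovery_cancer": {"label": "cancer", "counts": {">=3": 22, "2": 0, "1": 0, "0": 1}},
    "validation_presurgery": {"label": "cancer", "counts": {">=3": 32, "2": 10, "1": 13, "0": 25}},
    "validation_hcc": {"label": "cancer", "counts": {">=3": 26, "2": 9, "1": 7, "0": 21}},
    "validation_icc": {"label": "cancer", "counts": {">=3": 6, "2": 1, "1": 6, "0": 4}},
    "validation_control": {"label": "control", "counts": {">=3": 0, "2": 0, "1": 1, "0": 27}},
    "followup_postsurgery": {
      "label": "cancer",
      "counts": {">=3": 2, "2": 1, "1": 7, "0": 19},
      "positives_reported": 9,
      "note": "The published category row sums to 10 positives of 29, but the study text twice states 9 of 29 (31.0%) positive follow-up samples; the text ratio is treated as canonical for rate arithmetic."
    }
  },
  "size_crosstab": {
    "covariate": "tumor size",
    "groups": {
      ">=5cm": {">=3": 23, "2": 3, "1": 6, "0": 6},
      "3-5cm": {">=3": 6, "2": 1, "1": 2, "0": 8},
      "<3cm": {">=3": 1, "2": 3, "1": 4, "0": 10},
      "NA": {">=3": 2, "2": 3, "1": 1, "0": 1}
    },
    "collapsed_2x2_comment": ">=5cm vs <5cm, positive (>=1 altered segment) vs negative"
  }
}
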