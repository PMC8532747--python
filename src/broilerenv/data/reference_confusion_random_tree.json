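{
  "description": "Reference 4-class confusion matrix (predicted rows x true columns) reported for a random-tree classifier of the final rearing condition, with the metric values printed alongside it. Cells whose printed value is inconsistent with the matrix's own counts are flagged consistent=false and are excluded from equality checks.",
  "class_order": ["Excellent", "Good", "Moderate", "Inadequate"],
  "counts": [
    [427, 24, 7, 22],
    [0, 0, 0, 0],
    [0, 0, 10, 0],
    [5, 0, 0, 0]
  ],
  "printed_precision": {"Excellent": 89, "Good": 0, "Moderate": 54, "Inadequate": 0},
  "printed_recall": {"Excellent": 97, "Good": 0, "Moderate": 59, "Inadequate": 0},
  "printed_accuracy": 89,
  "printed_kappa": 0.72,
  "consistent_precision": {"Excellent": true, "Good": true, "Moderate": false, "Inadequate": true},
  "consistent_recall": {"Excellent": false, "Good": true, "Moderate": true, "Inadequate": true},
  "consistent_accuracy": false,
  "consistent_kappa": false
}
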