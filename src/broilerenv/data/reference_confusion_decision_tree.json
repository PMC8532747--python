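{
  "description": "Reference 4-class confusion matrix (predicted rows x true columns) reported for a gain-ratio decision-tree classifier of the final rearing condition, with the metric values printed alongside it. Cells whose printed value is inconsistent with the matrix's own counts under round-half-up integer percent are flagged consistent=false and are excluded from equality checks.",
  "class_order": ["Excellent", "Good", "Moderate", "Inadequate"],
  "counts": [
    [436, 0, 1, 0],
    [0, 24, 0, 0],
    [0, 0, 16, 0],
    [0, 0, 0, 22]
  ],
  "printed_precision": {"Excellent": 99, "Good": 100, "Moderate": 100, "Inadequate": 100},
  "printed_recall": {"Excellent": 100, "Good": 100, "Moderate": 94, "Inadequate": 100},
  "printed_accuracy": 99,
  "printed_kappa": 0.81,
  "consistent_precision": {"Excellent": false, "Good": true, "Moderate": true, "Inadequate": true},
  "consistent_recall": {"Excellent": true, "Good": true, "Moderate": true, "Inadequate": true},
  "consistent_accuracy": false,
  "consistent_kappa": false
}
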