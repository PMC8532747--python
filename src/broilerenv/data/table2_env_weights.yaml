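# Age-conditioned environmental weight bins: for each variable (T = dry-bulb
# temperature degC, RH = relative humidity %, AV = air velocity m/s) and each
# recorded broiler age (21/28/35/42 d), an ordered list of
#   [lower, upper, quality, weight]
# half-open intervals [lower, upper) carrying the quality class of the range
# and the integer weight (1-10) it contributes to the rearing-condition score.
#
# The bins are shipped exactly as published.  Known blemishes, repaired
# during canonicalization (each repair is logged in the ValidationReport):
#   * T has a gap [24, 25) at every age, and a gap [17, 18) at 28/35/42 d;
#     gaps are closed by extending the preceding bin's upper bound.
#   * AV at 21 d lists [0.5, 0.6) twice (Excellent/8 then Moderate/4); the
#     second, conflicting row is truncated away and the first kept.
#   * The T 28-d row [28, 39) is labelled Excellent yet carries weight 1;
#     the patch below coerces the label to Inadequate, matching every other
#     age's same bin.
env_bins:
  T:
    21:
      - [10, 16, Inadequate, 1]
      - [16, 18, Inadequate, 1]
      - [18, 24, Moderate, 4]
      - [25, 28, Excellent, 6]
      - [28, 39, Inadequate, 1]
    28:
      - [10, 16, Inadequate, 1]
      - [16, 17, Moderate, 3]
      - [18, 24, Excellent, 10]
      - [25, 28, Good, 5]
      - [28, 39, Excellent, 1]   # label patched to Inadequate below
    35:
      - [10, 16, Inadequate, 1]
      - [16, 17, Moderate, 3]
      - [18, 24, Excellent, 10]
      - [25, 28, Good, 5]
      - [28, 39, Inadequate, 1]
    42:
      - [10, 16, Inadequate, 1]
      - [16, 17, Moderate, 4]
      - [18, 24, Excellent, 8]
      - [25, 28, Moderate, 4]
      - [28, 39, Inadequate, 1]
  RH:
    21:
      - [30, 40, Inadequate, 1]
      - [40, 60, Moderate, 4]
      - [60, 70, Excellent, 8]
      - [70, 80, Good, 6]
      - [80, 90, Good, 6]
    28:
      - [30, 40, Inadequate, 1]
      - [40, 60, Moderate, 4]
      - [60, 70, Excellent, 8]
      - [70, 80, Good, 6]
      - [80, 90, Moderate, 4]
    35:
      - [30, 40, Inadequate, 1]
      - [40, 60, Moderate, 6]
      - [60, 70, Excellent, 9]
      - [70, 80, Good, 4]
      - [80, 90, Inadequate, 1]
    42:
      - [30, 40, Good, 6]
      - [40, 60, Excellent, 9]
      - [60, 70, Moderate, 4]
      - [70, 80, Inadequate, 4]   # weight 4 kept as published (other Inadequate rows carry 1)
      - [80, 90, Inadequate, 1]
  AV:
    21:
      - [0.0, 0.2, Inadequate, 1]
      - [0.2, 0.4, Good, 6]
      - [0.4, 0.5, Excellent, 8]
      - [0.5, 0.6, Excellent, 8]
      - [0.5, 0.6, Moderate, 4]   # duplicate interval as published; dropped by canonicalization
      - [0.6, .inf, Inadequate, 1]
    28:
      - [0.0, 0.5, Moderate, 3]
      - [0.5, 0.8, Good, 6]
      - [0.8, 0.9, Excellent, 8]
      - [0.9, 1.0, Excellent, 8]
      - [1.0, 1.2, Excellent, 8]
      - [1.2, .inf, Excellent, 8]
    35:
      - [0.0, 1.25, Inadequate, 1]
      - [1.25, 1.9, Good, 6]
      - [1.9, 2.0, Good, 6]
      - [2.0, 2.5, Good, 5]
      - [2.5, 3.0, Good, 8]
      - [3.0, .inf, Excellent, 5]
    42:
      - [0.0, 1.25, Inadequate, 1]
      - [1.25, 1.9, Moderate, 4]
      - [1.9, 2.0, Good, 6]
      - [2.0, 2.5, Good, 7]
      - [2.5, 3.0, Good, 8]
      - [3.0, .inf, Excellent, 5]

# Point repairs applied before the generic gap/overlap canonicalization.
patches:
  - variable: T
    age: 28
    lower: 28
    quality: Inadequate
    note: "weight-1 row relabelled Inadequate for consistency with all other ages"
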