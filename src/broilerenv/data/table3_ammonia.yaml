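# Ammonia (NH3, mg/m3) class cutpoints by recorded broiler age.
# Three ascending cutpoints (c1, c2, c3) partition [0, inf) into
#   [0, c1) Excellent, [c1, c2) Good, [c2, c3) Moderate, [c3, inf) Inadequate.
#
# The published interval notation is not well-formed; these cutpoints are the
# canonical monotone reading of the published numbers (kept configurable).
ammonia_cutpoints:
  21: [4.2, 8.3, 13.0]
  28: [4.2, 8.3, 13.0]
  35: [8.3, 11.8, 13.0]
  42: [8.3, 11.8, 13.0]
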