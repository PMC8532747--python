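# "Stress scenario" generator overrides: ammonia inflated so that all four
# NH3 quality classes receive substantial probability mass across the
# canonical cutpoints (4.2 / 8.3 / 11.8 / 13.0 mg/m3).  Used to exercise the
# ammonia-driven branches of the labeling rules and the tree miner; the
# default scenario keeps NH3 near 4 mg/m3 where Moderate/Inadequate ammonia
# is rare.
moments:
  NH3:
    21: [9.0, 4.5]
    28: [9.0, 4.5]
    35: [9.0, 4.5]
    42: [9.0, 4.5]
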