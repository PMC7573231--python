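{
 "trace_B_seed42": "028f77b92945a2e9b8c54d63074dfa23ed2aca0824e3a98e6e73399c78aefa08",
 "cohort_seed42": "48e965fc60f771e5fcd1d19adeda873b8b3e978c2ac45a152985b07d3fc25b23",
 "de_seed42": "f69debc675cce607e46cf86361771b2933ab564b6098769d8c12b7a780945001"
}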