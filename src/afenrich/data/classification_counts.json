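{
  "total_deleterious_missense": 20857,
  "by_min_alt_count": {
    "1": {"total": 2750, "tier1": 1969, "tier2": 650, "tier3": 131},
    "6": {"total": 339, "tier1": 240, "tier2": 74, "tier3": 25}
  }
}
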