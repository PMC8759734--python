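{
  "cost_eur": {"lower": 200, "upper": 500},
  "pain_net_change_pct": {"lower": 15, "upper": 25},
  "function_net_change_pct": {"lower": 15, "upper": 40},
  "supervised_sessions": {"lower": 0, "upper": 30},
  "period_weeks": {"lower": 12, "upper": 26}
}
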