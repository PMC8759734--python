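{
  "cost_eur": {"lower": 300, "upper": 600},
  "pain_net_change_pct": {"lower": 15, "upper": 30},
  "function_net_change_pct": {"lower": 15, "upper": 25},
  "supervised_sessions": {"lower": 0, "upper": 15},
  "period_weeks": {"lower": 8, "upper": 26}
}
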