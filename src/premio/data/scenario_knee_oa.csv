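id,study,exercise_type,cost_eur,pain_net_change_pct,function_net_change_pct,supervised_sessions,period_weeks,n_exercise,n_control
cheung-yoga,Cheung (synthetic values),yoga,520.0,22.0,18.0,12.0,12.0,18,18
krasilshchikov-mixed,Krasilshchikov (synthetic values),resistance+aerobic,480.0,28.0,38.0,24.0,12.0,20,20
braghin-strength,Braghin (synthetic values),strengthening,340.0,20.0,26.0,20.0,16.0,25,24
lin-proprioception,Lin (synthetic values),proprioceptive,300.0,17.0,22.0,18.0,20.0,36,36
fransen-taichi,Fransen (synthetic values),tai chi,220.0,12.0,20.0,6.0,10.0,28,28
obrien-home,O'Brien (synthetic values),home exercise,0.0,8.0,6.0,0.0,8.0,30,30
kauppila-individual,Kauppila (synthetic values),individual physiotherapy,1440.0,32.0,42.0,36.0,24.0,15,15
wang-aquatic,Wang (synthetic values),aquatic,600.0,18.0,11.0,15.0,8.0,26,26
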