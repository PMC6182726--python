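# Amitriptyline (parent, full-PBPK leg) and nortriptyline (metabolite,
# minimal-PBPK leg).  MW, Kp_ht and fu_ht are the published constants; the
# disposition parameters (Kp table, clearances, metabolite leg volumes) are
# plausible defaults chosen to give literature-consistent kinetics
# (AT Vss ~17 L/kg, blood clearance ~27 L/h; NT t1/2 ~26 h) and are
# deliberately config-driven.
schema: cardiotwin-compounds-1
parent:
  name: AT
  MW: 277.4
  Kp_ht: 11.77
  fu_ht: 0.0012
  BP: 0.86
  CL_int_h: 40.0
  CL_other: 0.0
  fm_metabolite: 0.5
  Kp_map:
    lung: 40.0
    adipose: 12.0
    bone: 8.0
    brain: 25.0
    gut: 20.0
    heart: 11.77
    kidney: 30.0
    liver: 25.0
    muscle: 20.0
    skin: 15.0
    rest: 20.0
metabolite:
  name: NT
  MW: 263.384
  Kp_ht: 35.63
  fu_ht: 0.001
  BP: 1.0
  CL_other: 25.0
  Kp_re: 22.0
  V_central: 50.0
  V_re: 40.0
  Q_re: 100.0
absorption:
  ka: 0.24
  t_lag: 1.33
  F: 0.459
  fa_Fg: 0.832
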