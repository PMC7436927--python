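{
 "gates": [
  {"name": "P1_PhlF", "repressor": "PhlF",
   "response": {"y_max": 5.12, "y_min": 0.01, "K": 0.15, "n": 2.4},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3},
  {"name": "Q1_QacR", "repressor": "QacR",
   "response": {"y_max": 4.52, "y_min": 0.04, "K": 0.97, "n": 4.3},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3},
  {"name": "A1_AmtR", "repressor": "AmtR",
   "response": {"y_max": 2.08, "y_min": 0.03, "K": 0.15, "n": 1.7},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3},
  {"name": "B3_BM3R1", "repressor": "BM3R1",
   "response": {"y_max": 0.65, "y_min": 0.01, "K": 0.40, "n": 2.7},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3},
  {"name": "F2_AmeRs", "repressor": "AmeRs",
   "response": {"y_max": 3.69, "y_min": 0.03, "K": 0.13, "n": 1.7},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3},
  {"name": "E1_BetI", "repressor": "BetI",
   "response": {"y_max": 2.25, "y_min": 0.25, "K": 1.25, "n": 3.8},
   "growth": {"intercept": 1.0, "slope": 0.0}, "noise_cv": 0.3}
 ],
 "sensors": [
  {"name": "P_Badmc", "inducer": "L-arabinose (mM)", "y_min": 0.04, "y_max": 3.33},
  {"name": "P_Tac", "inducer": "IPTG (uM)", "y_min": 0.02, "y_max": 4.20},
  {"name": "P_Tet", "inducer": "aTc (ng/ml)", "y_min": 0.02, "y_max": 5.41},
  {"name": "P_CymRC", "inducer": "4-isopropylbenzoic acid (uM)", "y_min": 0.19, "y_max": 2.39},
  {"name": "P_VanCC", "inducer": "vanillic acid (uM)", "y_min": 0.02, "y_max": 3.79},
  {"name": "P_Cin", "inducer": "OHC14 (uM)", "y_min": 0.01, "y_max": 4.38},
  {"name": "P_TtgR", "inducer": "naringenin (mM)", "y_min": 0.01, "y_max": 0.22}
 ],
 "constants": {
  "flux_per_rpu_per_dna": 0.019,
  "landing_pad_copy_number": 3.5,
  "rpug_per_rpu": 6.33
 },
 "growth_cutoff": 0.75
}
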