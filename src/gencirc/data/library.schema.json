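{
 "$comment": "Human-readable description of the gencirc gate-library JSON format. Numbers may be IEEE doubles or decimal strings.",
 "type": "object",
 "required": ["gates", "sensors"],
 "properties": {
  "gates": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "repressor", "response"],
    "properties": {
     "name": {"type": "string", "description": "unique gate identifier"},
     "repressor": {"type": "string", "description": "unique repressor identifier"},
     "response": {
      "type": "object",
      "required": ["y_max", "y_min", "K", "n"],
      "description": "repression Hill parameters in RPU_G: y = y_min + (y_max - y_min)/(1 + (x/K)^n); 0 <= y_min < y_max, K > 0, n > 0"
     },
     "growth": {
      "type": "object",
      "description": "linear relative-OD600 model vs gate input (RPU_G): intercept in (0, 1.5], slope per RPU_G; default neutral (1.0, 0.0)"
     },
     "noise_cv": {"type": "number", "description": "lognormal CV of output cytometry events; default 0.3"}
    }
   }
  },
  "sensors": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "y_min", "y_max"],
    "properties": {
     "name": {"type": "string"},
     "inducer": {"type": "string", "description": "inducer name + units"},
     "y_min": {"type": "number", "description": "OFF output promoter activity (RPU_G)"},
     "y_max": {"type": "number", "description": "ON output promoter activity (RPU_G); must exceed y_min"},
     "dose_response": {
      "type": "object",
      "description": "optional activation Hill: K_ind (inducer concentration), n_ind (dimensionless); absent => two-point OFF/ON model"
     }
    }
   }
  },
  "constants": {
   "type": "object",
   "description": "flux_per_rpu_per_dna (RNAP/s per RPU per DNA copy, default 0.019); landing_pad_copy_number (default 3.5); rpug_per_rpu (RPU_G per RPU divisor, default 6.33)"
  },
  "growth_cutoff": {"type": "number", "description": "minimum acceptable per-state growth score in [0, 1]; default 0.75"}
 }
}
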