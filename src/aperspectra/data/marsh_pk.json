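{
  "model": "three-compartment plasma pharmacokinetics with first-order effect-site equilibration",
  "reference": "Marsh B, White M, Morton N, Kenny GN. Pharmacokinetic model driven infusion of propofol in children. Br J Anaesth 1991; 67:41-48",
  "units": {"rate_constants": "1/min", "V1": "L/kg"},
  "k10": 0.119,
  "k12": 0.112,
  "k13": 0.0419,
  "k21": 0.055,
  "k31": 0.0033,
  "V1": 0.228,
  "keo": 1.21,
  "molar_mass_g_per_mol": 178.27
}
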