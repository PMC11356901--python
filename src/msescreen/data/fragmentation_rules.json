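{
  "version": 1,
  "comment": "Diagnostic fragmentation chemistry for post-targeted lipid screening. Neutral-loss masses are recomputed from the element mass table at load; the mass fields here are audit values.",
  "neutral_losses": [
    {"name": "H2O", "formula": "H2O", "mass": 18.010565, "classes": ["MFA", "DFA", "CAD"]},
    {"name": "CO2", "formula": "CO2", "mass": 43.989829, "classes": ["MFA", "DFA", "CAD"]},
    {"name": "HCOOH", "formula": "CH2O2", "mass": 46.005479, "classes": ["MFA", "DFA", "CAD"]},
    {"name": "H2O+CO2", "formula": "CH2O3", "mass": 62.000394, "classes": ["MFA", "DFA"]}
  ],
  "amide_headgroup_series": [
    {"ion": "C3H8NO+", "neutral": "C3H7NO"},
    {"ion": "C4H10NO+", "neutral": "C4H9NO"},
    {"ion": "C5H12NO+", "neutral": "C5H11NO"},
    {"ion": "C6H14NO+", "neutral": "C6H13NO"}
  ]
}
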