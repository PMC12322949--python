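{
  "comment": "Default six-recognizer calibration. The cognate sets are a reconstruction from the recognizers named in the kit documentation (LIV, YFW, E, R, and binders for Asn/Gln and Ala/Ser); the commercial kit's exact dye assignments are not public, so dye photophysics here are synthetic, chosen to be well separated in (intensity, lifetime).",
  "recognizers": [
    {"name": "LIV", "cognates": ["L", "I", "V"], "dye": "dye-647",
     "dye_intensity_mean": 3.0, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 1.2, "dye_lifetime_sd": 0.2},
    {"name": "YFW", "cognates": ["Y", "F", "W"], "dye": "dye-676",
     "dye_intensity_mean": 2.5, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 2.4, "dye_lifetime_sd": 0.2},
    {"name": "AS", "cognates": ["A", "S"], "dye": "dye-700",
     "dye_intensity_mean": 2.0, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 3.6, "dye_lifetime_sd": 0.2},
    {"name": "NQ", "cognates": ["N", "Q"], "dye": "dye-730",
     "dye_intensity_mean": 1.5, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 4.8, "dye_lifetime_sd": 0.2},
    {"name": "E", "cognates": ["E"], "dye": "dye-755",
     "dye_intensity_mean": 1.0, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 6.0, "dye_lifetime_sd": 0.2},
    {"name": "R", "cognates": ["R"], "dye": "dye-780",
     "dye_intensity_mean": 0.5, "dye_intensity_sd": 0.08,
     "dye_lifetime_mean": 7.2, "dye_lifetime_sd": 0.2}
  ],
  "kinetics": {
    "mean_interpulse": 1.0,
    "entries": [
      {"recognizer": "LIV", "residue": "L", "mean_pd_s": 0.35, "binding_prob": 0.9},
      {"recognizer": "LIV", "residue": "I", "mean_pd_s": 0.23, "binding_prob": 0.9},
      {"recognizer": "LIV", "residue": "V", "mean_pd_s": 0.038889, "binding_prob": 0.9},
      {"recognizer": "YFW", "residue": "Y", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "YFW", "residue": "F", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "YFW", "residue": "W", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "AS", "residue": "A", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "AS", "residue": "S", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "NQ", "residue": "N", "mean_pd_s": 1.0, "binding_prob": 0.9},
      {"recognizer": "NQ", "residue": "Q", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "E", "residue": "E", "mean_pd_s": 0.2, "binding_prob": 0.9},
      {"recognizer": "R", "residue": "R", "mean_pd_s": 0.2, "binding_prob": 0.9}
    ]
  },
  "ptm_modifiers": [
    {"residue": "Y", "ptm": "phospho", "binding_prob_factor": 0.1, "pd_factor": 1.0}
  ],
  "cleavage_mean_time_s": 120.0
}
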