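{
  "intercept_as_printed": 1216.0,
  "intercept_corrected": 0.001216,
  "coefficients": {
    "ALogP": 0.0021,
    "AATSC5m": -0.0006597,
    "MATS5c": -0.01453,
    "MATS4s": 0.06744,
    "GATS5m": 0.005535,
    "SCH-6": -0.03136,
    "VCH-5": 0.02516,
    "minHBd": -0.02316,
    "minHBint7": 0.003159,
    "nAtomLC": -0.001681,
    "nFRing": 0.001964,
    "nT10HeteroRing": 0.008021,
    "RDF40m": 0.0007442,
    "RDF45m": 3.947e-06,
    "RDF85m": 4.102e-05,
    "RDF115e": 1.163e-05,
    "E3m": -0.009327
  }
}
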