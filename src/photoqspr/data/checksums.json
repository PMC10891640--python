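{
 "printed_equation.json": "516ac66b15fc9b9473cf13ba01fc1c981c757be48c9dae0760cb84578fb453a1",
 "table2_kinetics.csv": "bfc83ff1d1739f51fb831aaba09e9e0a2a418b2a79176598cbb3516bbd314462",
 "table3_descriptors.csv": "718f1bed76974a2a8ecb5b52a9c0d64077710215e2ae53ac316fcd7eb8b26a43",
 "table4_validation.csv": "3977e5fb3053c84e80f2658c0e8a67d7855d8c136bb0ae3ffe94565f6438e558"
}
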