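{
  "description": "Published combined-least-squares estimates of the threshold growth-law parameters for three U87 glioblastoma monolayer growth curves (seeding densities 0.02, 0.06, 0.2; 0-120 h; density scaled by maximum packing density). One row per threshold M; M=1 gives the smallest combined SSE.",
  "units": {"r": "1/h", "R": "1/h", "alpha": "", "beta": "", "C0": "fraction of packing density", "sse": ""},
  "fits": [
    {"M": 0, "r": 0.0113, "R": 0.0262, "alpha": 0.174, "beta": 2.82e-06, "C0": [0.0250, 0.0661, 0.184], "sse": 0.0179},
    {"M": 1, "r": 0.0168, "R": 0.0345, "alpha": 0.0608, "beta": 0.0692, "C0": [0.0192, 0.0652, 0.188], "sse": 0.0154},
    {"M": 2, "r": 0.0180, "R": 0.0576, "alpha": 2.84e-05, "beta": 0.139, "C0": [0.0160, 0.0619, 0.191], "sse": 0.0169},
    {"M": 3, "r": 0.0206, "R": 0.0642, "alpha": 3.66e-09, "beta": 0.0892, "C0": [0.0126, 0.0534, 0.193], "sse": 0.0268},
    {"M": 4, "r": 0.0218, "R": 0.134, "alpha": 3.43e-09, "beta": 0.0623, "C0": [0.0112, 0.0489, 0.191], "sse": 0.0366},
    {"M": 5, "r": 0.0237, "R": 0.0110, "alpha": 3.73e-10, "beta": 2.34e-04, "C0": [0.00933, 0.0420, 0.183], "sse": 0.0571}
  ]
}
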