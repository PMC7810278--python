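{
  "comment": "Parametric multiplet tables for rendering basis and simulation FIDs. Shifts in ppm; relative amplitudes are unitless weights within a metabolite; phases in degrees; linewidth is FWHM in Hz. The edited GABA C4 resonance is a pseudo-triplet at 3.01 ppm (J ~ 7.3 Hz); GABA also contributes a C2 group near 2.28 ppm. The difference-spectrum basis holds the metabolites co-edited by the 1.9 ppm editing pulse.",
  "difference_basis": {
    "GABA": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.0,
      "lines": [
        [2.9529, 1.0, 0.0],
        [3.01, 1.0, 0.0],
        [3.0671, 1.0, 0.0],
        [2.2436, 0.55, 0.0],
        [2.28, 0.65, 0.0],
        [2.3164, 0.55, 0.0]
      ]
    },
    "Glu": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.5,
      "lines": [
        [3.7433, 0.9, 0.0],
        [3.75, 1.0, 0.0],
        [3.7567, 0.9, 0.0],
        [2.3344, 0.8, 0.0],
        [2.352, 1.0, 0.0],
        [2.3696, 0.8, 0.0]
      ]
    },
    "Gln": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.5,
      "lines": [
        [2.4329, 0.8, 0.0],
        [2.45, 1.0, 0.0],
        [2.4671, 0.8, 0.0],
        [3.77, 0.6, 0.0]
      ]
    },
    "NAA": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.0,
      "lines": [
        [2.008, 3.0, 0.0],
        [2.49, 0.4, 0.0],
        [2.67, 0.4, 0.0]
      ]
    },
    "NAAG": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.0,
      "lines": [
        [2.045, 3.0, 0.0],
        [2.527, 0.4, 0.0],
        [2.707, 0.4, 0.0]
      ]
    }
  },
  "off_singlets": {
    "tCho": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.5,
      "lines": [[3.185, 1.0, 0.0]]
    },
    "tCr": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.5,
      "lines": [[3.027, 1.0, 0.0]]
    },
    "tNAA": {
      "lineshape": "lorentzian",
      "linewidth_hz": 4.5,
      "lines": [[2.008, 1.0, 0.0]]
    }
  },
  "water": {
    "lineshape": "lorentzian",
    "linewidth_hz": 6.0,
    "lines": [[4.7, 1.0, 0.0]]
  }
}
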