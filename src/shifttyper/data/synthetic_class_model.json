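{
  "format": "shifttyper-synthetic-class-model",
  "version": 1,
  "comment": "Synthetic fixture defaults: per-residue-type shift means (ppm) loosely seeded from typical random-coil values, with diagonal standard deviations. These are test-fixture data, not database statistics.",
  "default_sd": {"HN": 0.25, "N": 2.5, "CO": 0.7, "CA": 0.7, "CB": 0.8, "HA": 0.15, "HB": 0.15},
  "means": {
    "A": {"HN": 8.25, "N": 123.8, "CO": 177.8, "CA": 52.5, "CB": 19.1, "HA": 4.32, "HB": 1.39},
    "C": {"HN": 8.32, "N": 118.8, "CO": 174.6, "CA": 58.2, "CB": 28.0, "HA": 4.55, "HB": 2.93},
    "D": {"HN": 8.34, "N": 120.4, "CO": 176.3, "CA": 54.2, "CB": 41.1, "HA": 4.64, "HB": 2.72},
    "E": {"HN": 8.42, "N": 120.7, "CO": 176.6, "CA": 56.6, "CB": 29.9, "HA": 4.35, "HB": 2.01},
    "F": {"HN": 8.30, "N": 120.3, "CO": 175.8, "CA": 57.7, "CB": 39.6, "HA": 4.62, "HB": 3.05},
    "G": {"HN": 8.33, "N": 108.8, "CO": 174.9, "CA": 45.1, "HA": 3.96},
    "H": {"HN": 8.42, "N": 118.2, "CO": 174.1, "CA": 55.0, "CB": 29.0, "HA": 4.73, "HB": 3.15},
    "I": {"HN": 8.00, "N": 120.5, "CO": 176.4, "CA": 61.1, "CB": 38.8, "HA": 4.17, "HB": 1.85},
    "K": {"HN": 8.29, "N": 120.4, "CO": 176.6, "CA": 56.2, "CB": 33.1, "HA": 4.32, "HB": 1.78},
    "L": {"HN": 8.16, "N": 121.8, "CO": 177.6, "CA": 55.1, "CB": 42.4, "HA": 4.34, "HB": 1.62},
    "M": {"HN": 8.28, "N": 119.6, "CO": 176.3, "CA": 55.4, "CB": 32.9, "HA": 4.48, "HB": 2.05},
    "N": {"HN": 8.40, "N": 118.7, "CO": 175.2, "CA": 53.1, "CB": 38.9, "HA": 4.74, "HB": 2.80},
    "P": {"N": 137.0, "CO": 177.3, "CA": 63.3, "CB": 32.1, "HA": 4.42, "HB": 2.05},
    "Q": {"HN": 8.32, "N": 119.8, "CO": 176.0, "CA": 55.7, "CB": 29.4, "HA": 4.34, "HB": 2.05},
    "R": {"HN": 8.27, "N": 120.5, "CO": 176.3, "CA": 56.0, "CB": 30.9, "HA": 4.34, "HB": 1.79},
    "S": {"HN": 8.31, "N": 115.7, "CO": 174.6, "CA": 58.3, "CB": 63.8, "HA": 4.47, "HB": 3.88},
    "T": {"HN": 8.15, "N": 113.6, "CO": 174.7, "CA": 61.8, "CB": 69.8, "HA": 4.35, "HB": 4.24},
    "V": {"HN": 8.03, "N": 119.2, "CO": 176.3, "CA": 62.2, "CB": 32.9, "HA": 4.12, "HB": 2.08},
    "W": {"HN": 8.25, "N": 121.3, "CO": 176.1, "CA": 57.5, "CB": 29.6, "HA": 4.66, "HB": 3.22},
    "Y": {"HN": 8.12, "N": 120.3, "CO": 175.9, "CA": 57.9, "CB": 38.8, "HA": 4.55, "HB": 2.98}
  }
}
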