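{
  "format": "shifttyper-atom-name-map",
  "version": 1,
  "comment": "Normalization of NMR-STAR atom names to the seven canonical shift names. Names in 'stereo_average' map stereo pairs onto one canonical name; multiple values are reduced by arithmetic mean.",
  "direct": {
    "H": "HN",
    "HN": "HN",
    "N": "N",
    "C": "CO",
    "CO": "CO",
    "CA": "CA",
    "CB": "CB",
    "HA": "HA",
    "HB": "HB"
  },
  "stereo_average": {
    "HA2": "HA",
    "HA3": "HA",
    "HB2": "HB",
    "HB3": "HB"
  }
}
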