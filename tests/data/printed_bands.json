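{
  "em310": {
    "retinol": "490,112",
    "arachidonic": "425,120",
    "oleic": "370,85",
    "linoleic": "417,92"
  },
  "em366": {
    "retinol": "490,112",
    "arachidonic": "470,93",
    "oleic": "462,90",
    "linoleic": "428,73"
  },
  "exc570": {
    "dominant": "330,60",
    "bilirubin_400": "400,35",
    "bilirubin_435": "435,40",
    "bilirubin_470": "470,70"
  }
}
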