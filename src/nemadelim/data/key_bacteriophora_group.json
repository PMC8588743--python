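{
  "name": "Infective-juvenile key to the closest species of the Bacteriophora-group (reconstruction compiled from the published diagnoses and comparative range tables; editable data, not code)",
  "stage": "IJ",
  "root": {
    "character": "T",
    "op": "ge",
    "threshold": 83,
    "if_true": {"species": "H. bacteriophora"},
    "if_false": {
      "character": "EP",
      "op": "ge",
      "threshold": 100,
      "if_true": {"species": "H. beicherriana"},
      "if_false": {
        "character": "NR",
        "op": "lt",
        "threshold": 67,
        "if_true": {"species": "H. ruandica"},
        "if_false": {"species": "H. zacatecana"}
      }
    }
  }
}
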