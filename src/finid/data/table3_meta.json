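{
  "relatives": {
    "Carcharodon carcharias": ["Lamna nasus", "Cetorhinus maximus"],
    "Carcharhinus longimanus": ["Sphyrna lewini", "Sphyrna mokarran", "Sphyrna zygaena"],
    "Cetorhinus maximus": ["Carcharodon carcharias", "Lamna nasus"],
    "Lamna nasus": ["Carcharodon carcharias", "Cetorhinus maximus"],
    "Rhincodon typus": ["Cetorhinus maximus"],
    "Sphyrna lewini": ["Sphyrna mokarran", "Sphyrna zygaena"],
    "Sphyrna mokarran": ["Sphyrna lewini", "Sphyrna zygaena"],
    "Sphyrna zygaena": ["Sphyrna lewini", "Sphyrna mokarran"]
  },
  "low_confidence_positions": [60]
}
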