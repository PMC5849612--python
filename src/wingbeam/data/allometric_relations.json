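[
  {
    "name": "basal_pterosaur_wingspan",
    "kind": "power-law",
    "a": 778.535,
    "b": 3.0,
    "x_definition": "wingspan in metres",
    "x_range": [0.25, 1.6],
    "source": "Witton (2008) span-mass relation for basal (non-pterodactyloid) pterosaurs; amplitude calibrated to the published Rhamphorhynchus reconstruction (0.496 m -> 95 g), isometric exponent"
  },
  {
    "name": "pterodactyloid_wingspan",
    "kind": "power-law",
    "a": 187.04,
    "b": 3.0,
    "x_definition": "wingspan in metres",
    "x_range": [1.0, 11.0],
    "source": "Witton (2008) span-mass relation for pterodactyloid pterosaurs; amplitude calibrated to the published Brasileodactylus reconstruction (3.270 m -> 6540 g), isometric exponent"
  },
  {
    "name": "crocodylian_total_length",
    "kind": "power-law",
    "a": 0.022,
    "b": 2.84,
    "x_definition": "total body length in cm",
    "x_range": [50, 500],
    "source": "Crocodylian length-mass scaling compiled from the ecological literature; no published reconstruction is available to pin the amplitude"
  }
]
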