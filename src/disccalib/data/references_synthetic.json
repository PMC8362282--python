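[
  {
    "indicator": "RoM",
    "direction": "flexion",
    "load_case": "rom_10Nm_100N",
    "mean": 16.71,
    "sd": 5.0,
    "units": "deg",
    "note": "synthetic placeholder: cadaveric flexion RoM target with a plausible in-vitro SD; replace the SD with real study values"
  },
  {
    "indicator": "RoM",
    "direction": "extension",
    "load_case": "rom_10Nm_100N",
    "mean": -16.24,
    "sd": 5.0,
    "units": "deg",
    "note": "synthetic placeholder: cadaveric extension RoM target with a plausible in-vitro SD; replace the SD with real study values"
  },
  {
    "indicator": "DC",
    "direction": "n/a",
    "load_case": "dc_1200N",
    "mean": 1.3,
    "sd": 0.3,
    "units": "mm",
    "note": "synthetic placeholder scatter around the surrogate operating point"
  },
  {
    "indicator": "IDP",
    "direction": "n/a",
    "load_case": "dc_1200N",
    "mean": 0.065,
    "sd": 0.02,
    "units": "MPa",
    "note": "synthetic placeholder for the nucleus-stress proxy, not a physiological pressure"
  },
  {
    "indicator": "FCF",
    "direction": "right extension",
    "load_case": "idp_fcf_7.5Nm",
    "mean": 60.0,
    "sd": 25.0,
    "units": "N",
    "note": "synthetic placeholder; facet force is never computed by the surrogate and is validated only from external values"
  }
]
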