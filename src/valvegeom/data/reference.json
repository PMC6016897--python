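{
  "yang_cadaveric": {
    "cusp_area": {"mean": 238.71, "sd": 63.47, "units": "mm^2"},
    "annulus_diameter": {"mean": 18.2, "sd": 3.2, "units": "mm"},
    "annulus_circumference": {"mean": 57.177, "sd": 10.053, "units": "mm"},
    "orifice_area": {"mean": 456.6, "sd": 106.62, "units": "mm^2"}
  },
  "cusp_morphometrics": {
    "left": {"width_mean": 21.61, "width_sd": 3.56, "height_mean": 11.78, "height_sd": 2.36},
    "right": {"width_mean": 21.58, "width_sd": 4.25, "height_mean": 12.03, "height_sd": 2.38},
    "anterior": {"width_mean": 21.41, "width_sd": 4.14, "height_mean": 12.05, "height_sd": 2.4}
  },
  "model_defaults": {
    "width_mm": 20.211,
    "max_height_mm": 14.2,
    "n_cusps": 3,
    "flap_to_valve_ratio": 1.55
  }
}
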