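{
  "provenance": "API/polymer/water parameter set for naproxen and venetoclax with PVPVA64 and water: melting properties, true densities, glass-transition temperatures, PC-SAFT pure-component parameters and temperature-dependent binary interaction coefficients, as published for this system.",
  "components": [
    {
      "name": "naproxen",
      "molar_mass": {"value": 230.26, "unit": "g/mol"},
      "segment_ratio": {"value": 0.0352, "unit": "mol/g"},
      "segment_diameter": {"value": 2.939, "unit": "angstrom"},
      "dispersion_energy": {"value": 229.45, "unit": "K"},
      "assoc_energy": {"value": 934.2, "unit": "K"},
      "assoc_volume": 0.02,
      "assoc_sites": [2, 2],
      "melting_T": {"value": 429.47, "unit": "K"},
      "melting_enthalpy": {"value": 31.50, "unit": "kJ/mol"},
      "delta_cp": {"value": 87.0, "unit": "J/mol/K"},
      "density": {"value": 1250.0, "unit": "kg/m^3"},
      "glass_T": {"value": 265.15, "unit": "K"}
    },
    {
      "name": "venetoclax",
      "molar_mass": {"value": 868.44, "unit": "g/mol"},
      "segment_ratio": {"value": 0.03938, "unit": "mol/g"},
      "segment_diameter": {"value": 2.546, "unit": "angstrom"},
      "dispersion_energy": {"value": 233.70, "unit": "K"},
      "assoc_energy": {"value": 0.0, "unit": "K"},
      "assoc_volume": null,
      "assoc_sites": [0, 0],
      "melting_T": {"value": 418.15, "unit": "K"},
      "melting_enthalpy": {"value": 59.9, "unit": "kJ/mol"},
      "delta_cp": null,
      "density": {"value": 1340.0, "unit": "kg/m^3"},
      "glass_T": {"value": 393.15, "unit": "K"}
    },
    {
      "name": "PVPVA64",
      "molar_mass": {"value": 65000.0, "unit": "g/mol"},
      "segment_ratio": {"value": 0.0372, "unit": "mol/g"},
      "segment_diameter": {"value": 2.947, "unit": "angstrom"},
      "dispersion_energy": {"value": 205.27, "unit": "K"},
      "assoc_energy": {"value": 0.0, "unit": "K"},
      "assoc_volume": 0.02,
      "assoc_sites": [653, 653],
      "melting_T": null,
      "melting_enthalpy": null,
      "delta_cp": null,
      "density": {"value": 1190.0, "unit": "kg/m^3"},
      "glass_T": {"value": 384.15, "unit": "K"}
    },
    {
      "name": "water",
      "molar_mass": {"value": 18.015, "unit": "g/mol"},
      "segment_ratio": {"value": 0.0669, "unit": "mol/g"},
      "segment_diameter": {"formula": "water_exponential", "coefficients": [2.7927, 10.11, -0.01755, -1.417, -0.01146], "unit": "angstrom"},
      "dispersion_energy": {"value": 353.95, "unit": "K"},
      "assoc_energy": {"value": 2425.7, "unit": "K"},
      "assoc_volume": 0.0451,
      "assoc_sites": [1, 1],
      "melting_T": null,
      "melting_enthalpy": null,
      "delta_cp": null,
      "density": {"value": 1000.0, "unit": "kg/m^3"},
      "glass_T": {"value": 138.00, "unit": "K"}
    }
  ],
  "interactions": [
    {"pair": ["PVPVA64", "water"], "kij_m": {"value": 0.0, "unit": "1/K"}, "kij_b": -0.1565},
    {"pair": ["naproxen", "water"], "kij_m": {"value": 0.000227, "unit": "1/K"}, "kij_b": -0.0612},
    {"pair": ["naproxen", "PVPVA64"], "kij_m": {"value": 0.0, "unit": "1/K"}, "kij_b": -0.0574},
    {"pair": ["venetoclax", "water"], "kij_m": {"value": 0.0, "unit": "1/K"}, "kij_b": -0.0283},
    {"pair": ["venetoclax", "PVPVA64"], "kij_m": {"value": -0.0000467, "unit": "1/K"}, "kij_b": 0.0075}
  ]
}
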