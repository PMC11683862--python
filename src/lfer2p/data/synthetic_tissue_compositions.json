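{
  "_comment": "SYNTHETIC representative tissue compositions. Mass fractions of the five sorptive phases (water, storage lipid, phospholipid, structural protein, albumin) for common mammalian tissues and cow milk, assembled from typical physiological composition values. These are stand-in values for literature composition tables that are not redistributed here; users reproducing a specific study should replace them with the source tables via an overlay file. Basis: mass fraction (kg/kg wet tissue); partition coefficients supplied to the multiphase model must be on a matching basis.",
  "basis": "mass_fraction",
  "tissues": {
    "plasma": {
      "f_water": 0.945, "f_storage_lipid": 0.003, "f_phospholipid": 0.002,
      "f_structural_protein": 0.005, "f_albumin": 0.045
    },
    "blood": {
      "f_water": 0.82, "f_storage_lipid": 0.003, "f_phospholipid": 0.003,
      "f_structural_protein": 0.14, "f_albumin": 0.034
    },
    "muscle": {
      "f_water": 0.76, "f_storage_lipid": 0.02, "f_phospholipid": 0.008,
      "f_structural_protein": 0.20, "f_albumin": 0.012
    },
    "liver": {
      "f_water": 0.71, "f_storage_lipid": 0.035, "f_phospholipid": 0.025,
      "f_structural_protein": 0.21, "f_albumin": 0.02
    },
    "kidney": {
      "f_water": 0.78, "f_storage_lipid": 0.02, "f_phospholipid": 0.016,
      "f_structural_protein": 0.17, "f_albumin": 0.014
    },
    "brain": {
      "f_water": 0.77, "f_storage_lipid": 0.05, "f_phospholipid": 0.06,
      "f_structural_protein": 0.11, "f_albumin": 0.01
    },
    "adipose": {
      "f_water": 0.15, "f_storage_lipid": 0.80, "f_phospholipid": 0.002,
      "f_structural_protein": 0.04, "f_albumin": 0.008
    },
    "milk": {
      "f_water": 0.921, "f_storage_lipid": 0.039, "f_phospholipid": 0.001,
      "f_structural_protein": 0.033, "f_albumin": 0.006
    }
  }
}
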