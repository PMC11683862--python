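{
  "_comment": "Published 2p-LFER coefficient sets: logK_phase-water = lambda1*logKow + lambda2*logKaw + lambda3. SEs are the published bootstrap standard errors (1000 resamples). lambda3 = 0.0 with intercept_dropped = true means the intercept was statistically indistinguishable from zero and the regression was repeated without it.",
  "phases": {
    "chicken_structural_protein": {
      "lambda1": 0.813, "se1": 0.049,
      "lambda2": -0.077, "se2": 0.024,
      "lambda3": -0.874, "se3": 0.223,
      "intercept_dropped": false,
      "n": 46, "r2": 0.882, "adj_r2": 0.877, "f_stat": 161.7, "rmse": 0.323,
      "source": "Khawar et al. 2024, J. Chem. Inf. Model. (chicken muscle protein)"
    },
    "fish_structural_protein": {
      "lambda1": 0.886, "se1": 0.055,
      "lambda2": -0.097, "se2": 0.027,
      "lambda3": -1.243, "se3": 0.246,
      "intercept_dropped": false,
      "n": 45, "r2": 0.870, "adj_r2": 0.864, "f_stat": 140.8, "rmse": 0.353,
      "source": "Khawar et al. 2024, J. Chem. Inf. Model. (fish muscle protein)"
    },
    "combined_structural_protein": {
      "lambda1": 0.851, "se1": 0.049,
      "lambda2": -0.092, "se2": 0.025,
      "lambda3": -1.080, "se3": 0.220,
      "intercept_dropped": false,
      "n": 51, "r2": 0.878, "adj_r2": 0.873, "f_stat": 173.3, "rmse": 0.334,
      "source": "Khawar et al. 2024, J. Chem. Inf. Model. (averaged chicken/fish protein)"
    },
    "bsa": {
      "lambda1": 0.788, "se1": 0.046,
      "lambda2": -0.053, "se2": 0.018,
      "lambda3": 0.0, "se3": null,
      "intercept_dropped": true,
      "n": 83, "r2": 0.760, "adj_r2": 0.759, "f_stat": 130.5, "rmse": 0.422,
      "source": "Khawar et al. 2024, J. Chem. Inf. Model. (bovine serum albumin)"
    },
    "phospholipid": {
      "lambda1": 1.070, "se1": 0.021,
      "lambda2": -0.056, "se2": 0.013,
      "lambda3": -0.247, "se3": 0.095,
      "intercept_dropped": false,
      "n": null, "r2": 0.953, "adj_r2": 0.952, "f_stat": 1293.0, "rmse": 0.414,
      "source": "Khawar et al. 2023 (phospholipid-water)"
    },
    "storage_lipid": {
      "lambda1": 1.102, "se1": 0.016,
      "lambda2": 0.069, "se2": 0.010,
      "lambda3": -0.236, "se3": 0.043,
      "intercept_dropped": false,
      "n": null, "r2": 0.971, "adj_r2": 0.970, "f_stat": 5046.0, "rmse": 0.375,
      "source": "Khawar et al. 2023 (storage lipid-water)"
    }
  },
  "synonyms": {
    "structural_protein": "combined_structural_protein",
    "combined structural proteins": "combined_structural_protein",
    "chicken structural protein": "chicken_structural_protein",
    "fish structural protein": "fish_structural_protein",
    "bovine albumin serum protein": "bsa",
    "bovine_serum_albumin": "bsa",
    "albumin": "bsa",
    "serum_albumin": "bsa",
    "storage lipid": "storage_lipid",
    "lipid": "storage_lipid"
  }
}
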