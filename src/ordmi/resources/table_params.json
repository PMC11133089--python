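{
  "_comment": "Generating parameter sets: per set and category count, item loadings, reference unique variances, and thresholds on the standardized latent-response scale (proportion-preserving). 'thresholds_standardized' marks sets whose tabulated thresholds are standardized and need rescaling by sqrt(lambda^2*psi+theta) to the raw latent-response scale; for the skewed sets the two scales coincide because lambda^2+theta = 1.",
  "negatively_skewed": {
    "thresholds_standardized": false,
    "2": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[-0.59], [-0.59], [-0.59], [-0.59], [-0.59], [-0.59], [-0.59], [-0.59], [-0.59], [-0.59]],
      "skewness": -1.0
    },
    "5": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15], [-1.55, -1.08, -0.55, 0.15]],
      "skewness": -1.0
    },
    "7": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3], [-1.65, -1.23, -0.92, -0.61, -0.28, 0.3]],
      "skewness": -1.0
    }
  },
  "positively_skewed": {
    "thresholds_standardized": false,
    "2": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[0.59], [0.59], [0.59], [0.59], [0.59], [0.59], [0.59], [0.59], [0.59], [0.59]],
      "skewness": 1.0
    },
    "5": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555], [-0.151, 0.553, 1.08, 1.555]],
      "skewness": 1.0
    },
    "7": {
      "loadings": [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6],
      "unique_variances": [0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64],
      "thresholds": [[-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645], [-0.305, 0.279, 0.613, 0.915, 1.227, 1.645]],
      "skewness": 1.0
    }
  },
  "BACS": {
    "thresholds_standardized": true,
    "2": {
      "loadings": [2.68, 2.16, 2.21, 1.83, 1.43, 1.38, 1.31],
      "unique_variances": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
      "thresholds": [[-2.92], [-2.66], [-2.13], [-2.01], [-2.37], [-1.41], [-1.41]],
      "skewness": null
    },
    "5": {
      "loadings": [2.68, 2.16, 2.21, 1.83, 1.43, 1.38, 1.31],
      "unique_variances": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
      "thresholds": [[-3.34, -1.84, -0.22, 2.27], [-3.29, -1.99, -0.69, 0.99], [-3.58, -1.9, -0.33, 1.32], [-3.31, -1.94, -0.41, 1.37], [-3.47, -1.88, -0.74, 0.57], [-2.09, -1.15, -0.34, 1.25], [-2.36, -1.1, -0.53, 0.77]],
      "skewness": null
    }
  }
}
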