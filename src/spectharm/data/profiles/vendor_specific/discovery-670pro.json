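{
  "name": "discovery-670pro",
  "psf_fwhm_mm": 6.4,
  "post_filter_fwhm_mm": 0.0,
  "sensitivity_cps_per_mbq": 72.0,
  "voxel_size_mm": [
    2.21,
    2.21,
    2.21
  ],
  "n_projections": 120,
  "calibration_factor": 0.075,
  "calibration_bias": 1.01,
  "size_degradation": {
    "small": {
      "count_scale": 1.0,
      "fwhm_add_mm": 0.0
    },
    "medium": {
      "count_scale": 0.6,
      "fwhm_add_mm": 1.0
    },
    "large": {
      "count_scale": 0.25,
      "fwhm_add_mm": 2.0
    }
  }
}
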