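{
  "$defs": {
    "SizeDegradation": {
      "description": "Extra image degradation for enlarged (high-BMI) phantom acquisitions.",
      "properties": {
        "count_scale": {
          "default": 1.0,
          "exclusiveMinimum": 0,
          "maximum": 1.0,
          "title": "Count Scale",
          "type": "number"
        },
        "fwhm_add_mm": {
          "default": 0.0,
          "minimum": 0,
          "title": "Fwhm Add Mm",
          "type": "number"
        }
      },
      "title": "SizeDegradation",
      "type": "object"
    }
  },
  "description": "Per-scanner imaging characteristics and calibration.\n\n``calibration_factor`` converts activity concentration to count rate\ndensity, in (cps/ml)/(kBq/ml).  ``calibration_bias`` is a unitless\nmultiplicative cross-calibration error applied at simulation time only;\na perfectly cross-calibrated system has bias 1.0.",
  "properties": {
    "name": {
      "title": "Name",
      "type": "string"
    },
    "psf_fwhm_mm": {
      "exclusiveMinimum": 0,
      "title": "Psf Fwhm Mm",
      "type": "number"
    },
    "post_filter_fwhm_mm": {
      "default": 0.0,
      "minimum": 0,
      "title": "Post Filter Fwhm Mm",
      "type": "number"
    },
    "sensitivity_cps_per_mbq": {
      "exclusiveMinimum": 0,
      "title": "Sensitivity Cps Per Mbq",
      "type": "number"
    },
    "voxel_size_mm": {
      "maxItems": 3,
      "minItems": 3,
      "prefixItems": [
        {
          "type": "number"
        },
        {
          "type": "number"
        },
        {
          "type": "number"
        }
      ],
      "title": "Voxel Size Mm",
      "type": "array"
    },
    "n_projections": {
      "default": 128,
      "minimum": 1,
      "title": "N Projections",
      "type": "integer"
    },
    "calibration_factor": {
      "exclusiveMinimum": 0,
      "title": "Calibration Factor",
      "type": "number"
    },
    "calibration_bias": {
      "default": 1.0,
      "exclusiveMinimum": 0,
      "title": "Calibration Bias",
      "type": "number"
    },
    "size_degradation": {
      "additionalProperties": {
        "$ref": "#/$defs/SizeDegradation"
      },
      "title": "Size Degradation",
      "type": "object"
    }
  },
  "required": [
    "name",
    "psf_fwhm_mm",
    "sensitivity_cps_per_mbq",
    "voxel_size_mm",
    "calibration_factor"
  ],
  "title": "SystemProfile",
  "type": "object"
}
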