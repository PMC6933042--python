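{
  "description": "Declarative description of one synthetic multi-system experiment.",
  "properties": {
    "phantoms": {
      "items": {
        "type": "string"
      },
      "title": "Phantoms",
      "type": "array"
    },
    "profile_mode": {
      "default": "vendor-specific",
      "title": "Profile Mode",
      "type": "string"
    },
    "n_replicates": {
      "default": 5,
      "minimum": 1,
      "title": "N Replicates",
      "type": "integer"
    },
    "time_per_projection_s": {
      "default": 20.0,
      "exclusiveMinimum": 0,
      "title": "Time Per Projection S",
      "type": "number"
    },
    "noiseless": {
      "default": false,
      "title": "Noiseless",
      "type": "boolean"
    },
    "base_seed": {
      "default": 0,
      "title": "Base Seed",
      "type": "integer"
    },
    "subsamples_per_axis": {
      "default": 5,
      "minimum": 1,
      "title": "Subsamples Per Axis",
      "type": "integer"
    },
    "out_dir": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Out Dir"
    }
  },
  "title": "ExperimentConfig",
  "type": "object"
}
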