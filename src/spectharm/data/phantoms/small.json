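{
  "name": "small",
  "total_volume_l": 9.7,
  "waist_circumference_cm": 85.0,
  "bmi_kg_m2": 25.0,
  "background_kbq_per_ml": 10.0,
  "body": {
    "width_mm": 300.0,
    "height_mm": 230.0,
    "length_mm": 168.26383495682947
  },
  "spheres": [
    {
      "label": "sphere_37mm",
      "inner_diameter_mm": 37.0,
      "center_mm": [
        57.2,
        0.0,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    },
    {
      "label": "sphere_28mm",
      "inner_diameter_mm": 28.0,
      "center_mm": [
        28.60000000000001,
        49.53665309646989,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    },
    {
      "label": "sphere_22mm",
      "inner_diameter_mm": 22.0,
      "center_mm": [
        -28.599999999999987,
        49.5366530964699,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    },
    {
      "label": "sphere_17mm",
      "inner_diameter_mm": 17.0,
      "center_mm": [
        -57.2,
        7.0049796911228604e-15,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    },
    {
      "label": "sphere_13mm",
      "inner_diameter_mm": 13.0,
      "center_mm": [
        -28.600000000000026,
        -49.53665309646988,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    },
    {
      "label": "sphere_10mm",
      "inner_diameter_mm": 10.0,
      "center_mm": [
        28.60000000000001,
        -49.53665309646989,
        0.0
      ],
      "activity_kbq_per_ml": 100.0
    }
  ]
}
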