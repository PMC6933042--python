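{
  "$defs": {
    "BodyOutline": {
      "description": "Torso-shaped interior: a 2D 'stadium' cross-section extruded axially.\n\nThe cross-section consists of two lateral semicircles of radius\n``height/2`` joined by straight top and bottom segments of length\n``width - height``; equivalently the set of points within ``height/2``\nof the central segment.  Coordinates are millimetres, origin at the\nphantom centroid, x lateral, y anterior-posterior, z axial.",
      "properties": {
        "width_mm": {
          "exclusiveMinimum": 0,
          "title": "Width Mm",
          "type": "number"
        },
        "height_mm": {
          "exclusiveMinimum": 0,
          "title": "Height Mm",
          "type": "number"
        },
        "length_mm": {
          "exclusiveMinimum": 0,
          "title": "Length Mm",
          "type": "number"
        }
      },
      "required": [
        "width_mm",
        "height_mm",
        "length_mm"
      ],
      "title": "BodyOutline",
      "type": "object"
    },
    "SphereSpec": {
      "description": "A fillable hollow sphere: label, inner diameter, position, fill concentration.",
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "inner_diameter_mm": {
          "exclusiveMinimum": 0,
          "title": "Inner Diameter Mm",
          "type": "number"
        },
        "center_mm": {
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
          "title": "Center Mm",
          "type": "array"
        },
        "activity_kbq_per_ml": {
          "minimum": 0,
          "title": "Activity Kbq Per Ml",
          "type": "number"
        }
      },
      "required": [
        "label",
        "inner_diameter_mm",
        "center_mm",
        "activity_kbq_per_ml"
      ],
      "title": "SphereSpec",
      "type": "object"
    }
  },
  "description": "Geometric and activity description of a fillable body phantom.",
  "properties": {
    "name": {
      "title": "Name",
      "type": "string"
    },
    "total_volume_l": {
      "exclusiveMinimum": 0,
      "title": "Total Volume L",
      "type": "number"
    },
    "waist_circumference_cm": {
      "exclusiveMinimum": 0,
      "title": "Waist Circumference Cm",
      "type": "number"
    },
    "bmi_kg_m2": {
      "exclusiveMinimum": 0,
      "title": "Bmi Kg M2",
      "type": "number"
    },
    "background_kbq_per_ml": {
      "minimum": 0,
      "title": "Background Kbq Per Ml",
      "type": "number"
    },
    "body": {
      "$ref": "#/$defs/BodyOutline"
    },
    "spheres": {
      "items": {
        "$ref": "#/$defs/SphereSpec"
      },
      "title": "Spheres",
      "type": "array"
    }
  },
  "required": [
    "name",
    "total_volume_l",
    "waist_circumference_cm",
    "bmi_kg_m2",
    "background_kbq_per_ml",
    "body",
    "spheres"
  ],
  "title": "PhantomSpec",
  "type": "object"
}
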