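{
  "$defs": {
    "ChargeTrend": {
      "properties": {
        "intercept": {
          "title": "Intercept",
          "type": "number"
        },
        "n_materials": {
          "title": "N Materials",
          "type": "integer"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "slope": {
          "title": "Slope",
          "type": "number"
        }
      },
      "required": [
        "slope",
        "intercept",
        "r_squared",
        "n_materials"
      ],
      "title": "ChargeTrend",
      "type": "object"
    },
    "ExperimentRecord": {
      "properties": {
        "file": {
          "title": "File",
          "type": "string"
        },
        "j0": {
          "title": "J0",
          "type": "number"
        },
        "j0_se": {
          "title": "J0 Se",
          "type": "number"
        },
        "n_points": {
          "title": "N Points",
          "type": "integer"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "sha256": {
          "title": "Sha256",
          "type": "string"
        },
        "sigma": {
          "title": "Sigma",
          "type": "number"
        }
      },
      "required": [
        "file",
        "sha256",
        "sigma",
        "j0",
        "j0_se",
        "r_squared",
        "n_points"
      ],
      "title": "ExperimentRecord",
      "type": "object"
    },
    "MaterialRecord": {
      "properties": {
        "b": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "B"
        },
        "b_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "B Se"
        },
        "charge": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Charge"
        },
        "error": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Error"
        },
        "experiments": {
          "items": {
            "$ref": "#/$defs/ExperimentRecord"
          },
          "title": "Experiments",
          "type": "array"
        },
        "gamma_net": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gamma Net"
        },
        "gamma_net_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gamma Net Se"
        },
        "ln_a": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ln A"
        },
        "ln_a_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ln A Se"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "r_squared": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "R Squared"
        }
      },
      "required": [
        "name"
      ],
      "title": "MaterialRecord",
      "type": "object"
    }
  },
  "description": "Schema of the pipeline's JSON output (shipped as report.schema.json).",
  "properties": {
    "charge_trend": {
      "anyOf": [
        {
          "$ref": "#/$defs/ChargeTrend"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "constants": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Constants",
      "type": "object"
    },
    "materials": {
      "items": {
        "$ref": "#/$defs/MaterialRecord"
      },
      "title": "Materials",
      "type": "array"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "version",
    "constants"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
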