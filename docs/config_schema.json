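{
  "$defs": {
    "AxisModel": {
      "additionalProperties": false,
      "properties": {
        "count": {
          "minimum": 2,
          "title": "Count",
          "type": "integer"
        },
        "name": {
          "enum": [
            "a_A2",
            "a_B2"
          ],
          "title": "Name",
          "type": "string"
        },
        "start": {
          "exclusiveMinimum": 0,
          "title": "Start",
          "type": "number"
        },
        "stop": {
          "exclusiveMinimum": 0,
          "title": "Stop",
          "type": "number"
        }
      },
      "required": [
        "name",
        "start",
        "stop",
        "count"
      ],
      "title": "AxisModel",
      "type": "object"
    },
    "CellTypeModel": {
      "additionalProperties": false,
      "properties": {
        "a_A": {
          "exclusiveMinimum": 0,
          "title": "A A",
          "type": "number"
        },
        "a_B": {
          "exclusiveMinimum": 0,
          "title": "A B",
          "type": "number"
        },
        "k": {
          "default": 1.0,
          "exclusiveMinimum": 0,
          "title": "K",
          "type": "number"
        },
        "manipulator": {
          "default": false,
          "title": "Manipulator",
          "type": "boolean"
        },
        "s_A": {
          "default": 1.0,
          "minimum": 0,
          "title": "S A",
          "type": "number"
        },
        "s_B": {
          "default": 1.0,
          "minimum": 0,
          "title": "S B",
          "type": "number"
        }
      },
      "required": [
        "a_A",
        "a_B"
      ],
      "title": "CellTypeModel",
      "type": "object"
    },
    "MetapopModel": {
      "additionalProperties": false,
      "properties": {
        "D": {
          "default": 3.0,
          "minimum": 0,
          "title": "D",
          "type": "number"
        },
        "curve_points": {
          "default": 81,
          "minimum": 11,
          "title": "Curve Points",
          "type": "integer"
        },
        "freq_tol": {
          "default": 1e-10,
          "exclusiveMinimum": 0,
          "title": "Freq Tol",
          "type": "number"
        },
        "initial_freqs": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Initial Freqs"
        },
        "mu": {
          "default": 0.05,
          "exclusiveMinimum": 0,
          "title": "Mu",
          "type": "number"
        },
        "n_patches": {
          "default": 100000,
          "minimum": 1,
          "title": "N Patches",
          "type": "integer"
        },
        "pairing": {
          "default": "expectation",
          "enum": [
            "expectation",
            "stochastic"
          ],
          "title": "Pairing",
          "type": "string"
        },
        "patch_growth_time": {
          "default": 12.5,
          "exclusiveMinimum": 0,
          "title": "Patch Growth Time",
          "type": "number"
        },
        "rounds_max": {
          "default": 500,
          "minimum": 1,
          "title": "Rounds Max",
          "type": "integer"
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
        "variants": {
          "items": {
            "$ref": "#/$defs/CellTypeModel"
          },
          "title": "Variants",
          "type": "array"
        }
      },
      "required": [
        "variants"
      ],
      "title": "MetapopModel",
      "type": "object"
    },
    "TradeModel": {
      "additionalProperties": false,
      "properties": {
        "D": {
          "default": 3.0,
          "minimum": 0,
          "title": "D",
          "type": "number"
        },
        "budget": {
          "default": 1.0,
          "exclusiveMinimum": 0,
          "title": "Budget",
          "type": "number"
        },
        "mu": {
          "default": 0.05,
          "exclusiveMinimum": 0,
          "title": "Mu",
          "type": "number"
        },
        "type1": {
          "$ref": "#/$defs/CellTypeModel",
          "default": {
            "a_A": 1.0,
            "a_B": 1.0,
            "k": 1.0,
            "manipulator": false,
            "s_A": 1.0,
            "s_B": 1.0
          }
        },
        "type2": {
          "$ref": "#/$defs/CellTypeModel",
          "default": {
            "a_A": 0.67,
            "a_B": 1.49,
            "k": 1.0,
            "manipulator": false,
            "s_A": 1.0,
            "s_B": 1.0
          }
        }
      },
      "title": "TradeModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level run configuration shared by all CLI subcommands.",
  "properties": {
    "axes": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/AxisModel"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Axes"
    },
    "log_level": {
      "default": "INFO",
      "title": "Log Level",
      "type": "string"
    },
    "metapop": {
      "anyOf": [
        {
          "$ref": "#/$defs/MetapopModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "output": {
      "default": "results",
      "title": "Output",
      "type": "string"
    },
    "scan_points": {
      "default": 41,
      "minimum": 5,
      "title": "Scan Points",
      "type": "integer"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "trade": {
      "$ref": "#/$defs/TradeModel",
      "default": {
        "D": 3.0,
        "budget": 1.0,
        "mu": 0.05,
        "type1": {
          "a_A": 1.0,
          "a_B": 1.0,
          "k": 1.0,
          "manipulator": false,
          "s_A": 1.0,
          "s_B": 1.0
        },
        "type2": {
          "a_A": 0.67,
          "a_B": 1.49,
          "k": 1.0,
          "manipulator": false,
          "s_A": 1.0,
          "s_B": 1.0
        }
      }
    }
  },
  "title": "RunConfig",
  "type": "object"
}
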