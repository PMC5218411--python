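{
  "$defs": {
    "AssociationSummary": {
      "properties": {
        "mode": {
          "title": "Mode",
          "type": "string"
        },
        "n_perm": {
          "title": "N Perm",
          "type": "integer"
        },
        "null_mean": {
          "title": "Null Mean",
          "type": "number"
        },
        "null_sd": {
          "title": "Null Sd",
          "type": "number"
        },
        "observed": {
          "title": "Observed",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "scheme": {
          "title": "Scheme",
          "type": "string"
        },
        "z_score": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Z Score"
        }
      },
      "required": [
        "observed",
        "null_mean",
        "null_sd",
        "z_score",
        "p_value",
        "n_perm",
        "mode",
        "scheme"
      ],
      "title": "AssociationSummary",
      "type": "object"
    },
    "ContactsSummary": {
      "properties": {
        "decay_exponent_estimate": {
          "title": "Decay Exponent Estimate",
          "type": "number"
        },
        "fraction_gc_poor": {
          "title": "Fraction Gc Poor",
          "type": "number"
        },
        "fraction_gc_rich": {
          "title": "Fraction Gc Rich",
          "type": "number"
        },
        "longrange_poor_rich_ratio": {
          "title": "Longrange Poor Rich Ratio",
          "type": "number"
        },
        "n_top_bins": {
          "title": "N Top Bins",
          "type": "integer"
        }
      },
      "required": [
        "decay_exponent_estimate",
        "longrange_poor_rich_ratio",
        "fraction_gc_rich",
        "fraction_gc_poor",
        "n_top_bins"
      ],
      "title": "ContactsSummary",
      "type": "object"
    },
    "LocalZSummary": {
      "properties": {
        "classification": {
          "title": "Classification",
          "type": "string"
        },
        "max_shift": {
          "title": "Max Shift",
          "type": "integer"
        },
        "peak_sharpness": {
          "title": "Peak Sharpness",
          "type": "number"
        },
        "step": {
          "title": "Step",
          "type": "integer"
        },
        "z_at_zero": {
          "title": "Z At Zero",
          "type": "number"
        }
      },
      "required": [
        "z_at_zero",
        "peak_sharpness",
        "classification",
        "max_shift",
        "step"
      ],
      "title": "LocalZSummary",
      "type": "object"
    },
    "SegmentationSummary": {
      "properties": {
        "boundary_recall": {
          "title": "Boundary Recall",
          "type": "number"
        },
        "bp_accuracy": {
          "title": "Bp Accuracy",
          "type": "number"
        },
        "n_isochores": {
          "title": "N Isochores",
          "type": "integer"
        }
      },
      "required": [
        "n_isochores",
        "boundary_recall",
        "bp_accuracy"
      ],
      "title": "SegmentationSummary",
      "type": "object"
    },
    "SyntenySummary": {
      "properties": {
        "max_span": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Max Span"
        },
        "mean_span": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mean Span"
        },
        "min_span": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Min Span"
        },
        "n_blocks": {
          "title": "N Blocks",
          "type": "integer"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "n_true_blocks": {
          "title": "N True Blocks",
          "type": "integer"
        },
        "pearson_r": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Pearson R"
        },
        "spearman_rho": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Spearman Rho"
        }
      },
      "required": [
        "n_blocks",
        "mean_span",
        "min_span",
        "max_span",
        "n_true_blocks",
        "pearson_r",
        "spearman_rho",
        "n_pairs"
      ],
      "title": "SyntenySummary",
      "type": "object"
    }
  },
  "properties": {
    "concordance": {
      "additionalProperties": true,
      "title": "Concordance",
      "type": "object"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "contacts": {
      "$ref": "#/$defs/ContactsSummary"
    },
    "ctcf_density": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Ctcf Density",
      "type": "array"
    },
    "lad_association": {
      "$ref": "#/$defs/AssociationSummary"
    },
    "lad_cf": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Lad Cf",
      "type": "array"
    },
    "outputs": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "segmentation": {
      "$ref": "#/$defs/SegmentationSummary"
    },
    "synteny": {
      "$ref": "#/$defs/SyntenySummary"
    },
    "tad_association": {
      "$ref": "#/$defs/AssociationSummary"
    },
    "tad_localz": {
      "$ref": "#/$defs/LocalZSummary"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "version",
    "seed",
    "config",
    "outputs",
    "segmentation",
    "tad_association",
    "lad_association",
    "tad_localz",
    "synteny",
    "contacts",
    "concordance",
    "lad_cf",
    "ctcf_density"
  ],
  "title": "AnalysisReport",
  "type": "object"
}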