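{
  "$defs": {
    "ArmYearOneProbs": {
      "additionalProperties": false,
      "description": "First-year event probabilities for one treatment arm.\n\nThe four events (nonfatal MI, nonfatal stroke, nonfatal unstable angina,\nall-cause death) are mutually exclusive branches of the year-1 decision\ntree; the residual fraction remains event-free.",
      "properties": {
        "p_nonfatal_mi": {
          "$ref": "#/$defs/Ranged"
        },
        "p_nonfatal_stroke": {
          "$ref": "#/$defs/Ranged"
        },
        "p_nonfatal_ua": {
          "$ref": "#/$defs/Ranged"
        },
        "p_death": {
          "$ref": "#/$defs/Ranged"
        }
      },
      "required": [
        "p_nonfatal_mi",
        "p_nonfatal_stroke",
        "p_nonfatal_ua",
        "p_death"
      ],
      "title": "ArmYearOneProbs",
      "type": "object"
    },
    "EventFreeProbs": {
      "additionalProperties": false,
      "description": "Annual risks for event-free patients in the Markov part.",
      "properties": {
        "p_mi": {
          "$ref": "#/$defs/Ranged"
        },
        "p_stroke": {
          "$ref": "#/$defs/Ranged"
        },
        "p_ua": {
          "$ref": "#/$defs/Ranged"
        },
        "p_death": {
          "$ref": "#/$defs/Ranged"
        }
      },
      "required": [
        "p_mi",
        "p_stroke",
        "p_ua",
        "p_death"
      ],
      "title": "EventFreeProbs",
      "type": "object"
    },
    "LongTermProbs": {
      "additionalProperties": false,
      "description": "All transition probabilities of the long-term Markov model.",
      "properties": {
        "event_free": {
          "$ref": "#/$defs/EventFreeProbs"
        },
        "post_mi": {
          "$ref": "#/$defs/PostEventProbs"
        },
        "post_ua": {
          "$ref": "#/$defs/PostEventProbs"
        },
        "post_stroke": {
          "$ref": "#/$defs/PostEventProbs"
        },
        "age_mace_or_per_10y": {
          "$ref": "#/$defs/Ranged"
        }
      },
      "required": [
        "event_free",
        "post_mi",
        "post_ua",
        "post_stroke",
        "age_mace_or_per_10y"
      ],
      "title": "LongTermProbs",
      "type": "object"
    },
    "ModelSettings": {
      "additionalProperties": false,
      "description": "Run settings and accounting conventions.\n\n``half_cycle`` selects the half-cycle correction applied to per-cycle\nrewards: ``trapezoid`` (default; half reward for the first cycle, mean\nof adjacent end-of-cycle rewards thereafter), ``entry-half`` (half\nreward for the first cycle, full end-of-cycle rewards thereafter) or\n``none``. ``disutility_mode`` controls whether event disutilities are\nsubtracted every year spent in an event or post-event state\n(``persistent``, default) or only in the event year (``one-off``).",
      "properties": {
        "horizon_years": {
          "default": 10,
          "minimum": 1,
          "title": "Horizon Years",
          "type": "integer"
        },
        "cycle_length_years": {
          "default": 1.0,
          "title": "Cycle Length Years",
          "type": "number"
        },
        "discount_rate": {
          "default": 0.035,
          "minimum": 0.0,
          "title": "Discount Rate",
          "type": "number"
        },
        "half_cycle": {
          "default": "trapezoid",
          "enum": [
            "trapezoid",
            "entry-half",
            "none"
          ],
          "title": "Half Cycle",
          "type": "string"
        },
        "disutility_mode": {
          "default": "persistent",
          "enum": [
            "persistent",
            "one-off"
          ],
          "title": "Disutility Mode",
          "type": "string"
        },
        "apply_age_or": {
          "default": false,
          "title": "Apply Age Or",
          "type": "boolean"
        },
        "add_background_mortality": {
          "default": false,
          "title": "Add Background Mortality",
          "type": "boolean"
        },
        "cohort_size": {
          "default": 1000,
          "minimum": 1,
          "title": "Cohort Size",
          "type": "integer"
        }
      },
      "title": "ModelSettings",
      "type": "object"
    },
    "PostEventProbs": {
      "additionalProperties": false,
      "description": "Annual risks after a nonfatal event, split by tenure.\n\n``*_y1`` applies in the first year after the event (the tunnel state),\n``*_later`` from the second year onward (the chronic post-event state).",
      "properties": {
        "p_death_y1": {
          "$ref": "#/$defs/Ranged"
        },
        "p_death_later": {
          "$ref": "#/$defs/Ranged"
        },
        "p_mi_y1": {
          "$ref": "#/$defs/Ranged"
        },
        "p_mi_later": {
          "$ref": "#/$defs/Ranged"
        },
        "p_stroke_y1": {
          "$ref": "#/$defs/Ranged"
        },
        "p_stroke_later": {
          "$ref": "#/$defs/Ranged"
        }
      },
      "required": [
        "p_death_y1",
        "p_death_later",
        "p_mi_y1",
        "p_mi_later",
        "p_stroke_y1",
        "p_stroke_later"
      ],
      "title": "PostEventProbs",
      "type": "object"
    },
    "Ranged": {
      "additionalProperties": false,
      "description": "A scalar parameter with an optional (low, high) sensitivity range.",
      "properties": {
        "base": {
          "title": "Base",
          "type": "number"
        },
        "low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Low"
        },
        "high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "High"
        }
      },
      "required": [
        "base"
      ],
      "title": "Ranged",
      "type": "object"
    },
    "UtilitySet": {
      "additionalProperties": false,
      "description": "Annual utility weights and event disutilities.\n\nUtilities are on the EQ-5D scale (0 = death, 1 = full health). Event\nstates are valued as the arm's event-free utility minus the event's\ndisutility; death has utility 0.",
      "properties": {
        "u_event_free_chm": {
          "$ref": "#/$defs/Ranged"
        },
        "u_event_free_conv": {
          "$ref": "#/$defs/Ranged"
        },
        "d_mi": {
          "$ref": "#/$defs/Ranged"
        },
        "d_stroke": {
          "$ref": "#/$defs/Ranged"
        },
        "d_ua": {
          "$ref": "#/$defs/Ranged"
        },
        "d_death": {
          "default": 0.0,
          "title": "D Death",
          "type": "number"
        }
      },
      "required": [
        "u_event_free_chm",
        "u_event_free_conv",
        "d_mi",
        "d_stroke",
        "d_ua"
      ],
      "title": "UtilitySet",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "The full model input: both arms, long-term risks, utilities, settings.",
  "properties": {
    "chm_arm": {
      "$ref": "#/$defs/ArmYearOneProbs"
    },
    "conv_arm": {
      "$ref": "#/$defs/ArmYearOneProbs"
    },
    "long_term": {
      "$ref": "#/$defs/LongTermProbs"
    },
    "utilities": {
      "$ref": "#/$defs/UtilitySet"
    },
    "settings": {
      "$ref": "#/$defs/ModelSettings"
    }
  },
  "required": [
    "chm_arm",
    "conv_arm",
    "long_term",
    "utilities"
  ],
  "title": "ParameterSet",
  "type": "object"
}
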