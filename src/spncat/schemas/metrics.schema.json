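{
 "$defs": {
  "BiasMetrics": {
   "properties": {
    "egger": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Egger",
     "type": "object"
    },
    "group_comparison": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Group Comparison",
     "type": "object"
    },
    "meta": {
     "additionalProperties": {
      "additionalProperties": {
       "type": "number"
      },
      "type": "object"
     },
     "title": "Meta",
     "type": "object"
    },
    "n_significant": {
     "title": "N Significant",
     "type": "integer"
    }
   },
   "required": [
    "group_comparison",
    "meta",
    "egger",
    "n_significant"
   ],
   "title": "BiasMetrics",
   "type": "object"
  },
  "PowerMetrics": {
   "properties": {
    "amplitude_regression": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Amplitude Regression",
     "type": "object"
    },
    "binomial_critical_24": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "title": "Binomial Critical 24"
    },
    "binomial_critical_48": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "title": "Binomial Critical 48"
    },
    "effect_model": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Effect Model",
     "type": "object"
    }
   },
   "required": [
    "effect_model",
    "amplitude_regression",
    "binomial_critical_24",
    "binomial_critical_48"
   ],
   "title": "PowerMetrics",
   "type": "object"
  },
  "StClusterMetrics": {
   "properties": {
    "apriori_datadriven_r": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Apriori Datadriven R"
    },
    "n_experiments": {
     "title": "N Experiments",
     "type": "integer"
    },
    "n_with_cluster": {
     "title": "N With Cluster",
     "type": "integer"
    }
   },
   "required": [
    "n_experiments",
    "n_with_cluster",
    "apriori_datadriven_r"
   ],
   "title": "StClusterMetrics",
   "type": "object"
  },
  "VibrationMetrics": {
   "properties": {
    "chi_square": {
     "anyOf": [
      {
       "additionalProperties": {
        "type": "number"
       },
       "type": "object"
      },
      {
       "type": "null"
      }
     ],
     "title": "Chi Square"
    },
    "correlation_range": {
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Correlation Range",
     "type": "array"
    },
    "significance_counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Significance Counts",
     "type": "object"
    }
   },
   "required": [
    "significance_counts",
    "chi_square",
    "correlation_range"
   ],
   "title": "VibrationMetrics",
   "type": "object"
  }
 },
 "properties": {
  "bias": {
   "anyOf": [
    {
     "$ref": "#/$defs/BiasMetrics"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "power": {
   "anyOf": [
    {
     "$ref": "#/$defs/PowerMetrics"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "stcluster": {
   "anyOf": [
    {
     "$ref": "#/$defs/StClusterMetrics"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "vibration": {
   "anyOf": [
    {
     "$ref": "#/$defs/VibrationMetrics"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  }
 },
 "title": "Metrics",
 "type": "object"
}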