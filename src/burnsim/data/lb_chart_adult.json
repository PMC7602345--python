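{
  "schema_version": 1,
  "description": "Standard adult Lund-Browder chart: per-region fractions of total body surface area. Values are the textbook adult column; age bands for infants/children can be added as additional keys.",
  "age_bands": {
    "adult": {
      "head_anterior": {"surface_fraction": 0.035, "side": "anterior"},
      "head_posterior": {"surface_fraction": 0.035, "side": "posterior"},
      "neck_anterior": {"surface_fraction": 0.01, "side": "anterior"},
      "neck_posterior": {"surface_fraction": 0.01, "side": "posterior"},
      "trunk_anterior": {"surface_fraction": 0.13, "side": "anterior"},
      "trunk_posterior": {"surface_fraction": 0.13, "side": "posterior"},
      "buttock_right": {"surface_fraction": 0.025, "side": "posterior"},
      "buttock_left": {"surface_fraction": 0.025, "side": "posterior"},
      "genitalia": {"surface_fraction": 0.01, "side": "anterior"},
      "upper_arm_right": {"surface_fraction": 0.04},
      "upper_arm_left": {"surface_fraction": 0.04},
      "lower_arm_right": {"surface_fraction": 0.03},
      "lower_arm_left": {"surface_fraction": 0.03},
      "hand_right": {"surface_fraction": 0.025},
      "hand_left": {"surface_fraction": 0.025},
      "thigh_right": {"surface_fraction": 0.095},
      "thigh_left": {"surface_fraction": 0.095},
      "leg_right": {"surface_fraction": 0.07},
      "leg_left": {"surface_fraction": 0.07},
      "foot_right": {"surface_fraction": 0.035},
      "foot_left": {"surface_fraction": 0.035}
    }
  }
}
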