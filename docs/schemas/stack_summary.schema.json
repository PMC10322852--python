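{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cryoslice stack-calibration summary",
  "type": "object",
  "required": [
    "tool_version",
    "n_components_native",
    "estimated_cell_intensity",
    "estimated_attenuation_cm1",
    "breakpoint_um"
  ],
  "properties": {
    "tool_version": {"type": "string"},
    "n_components_native": {"type": "integer"},
    "estimated_cell_intensity": {"type": ["number", "null"]},
    "estimated_attenuation_cm1": {"type": ["number", "null"]},
    "recommended_x_optimal_um": {"type": "number"},
    "sensitivity_at_thickness": {"type": "number"},
    "correction_factor": {"type": "number"},
    "breakpoint_um": {"type": ["number", "null"]}
  }
}
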