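{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cryoslice sweep summary",
  "type": "object",
  "required": ["tool_version", "mode", "seeds", "parameters", "breakpoint_um"],
  "properties": {
    "tool_version": {"type": "string"},
    "mode": {
      "enum": ["thickness", "intensity", "overlap", "mu-variation", "intensity-variation"]
    },
    "seeds": {"type": "array", "items": {"type": "integer"}},
    "parameters": {
      "type": "object",
      "required": [
        "intensity", "mu_cm1", "threshold", "volume_thickness_um",
        "sigma", "density_cells_per_cm2", "area_cm2"
      ]
    },
    "breakpoint_um": {"type": ["number", "null"]},
    "x_optimal_analytic_um": {"type": "number"},
    "loglog_slope_suboptimal": {"type": "number"}
  }
}
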