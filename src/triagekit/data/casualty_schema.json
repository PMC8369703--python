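{
  "title": "Casualty assessment record",
  "description": "Column contract for casualty CSV files (one row per casualty, fixed header) and JSON files (array of objects with the same field names). Ternary fields take yes/no/unknown (empty cell = unknown); numeric vitals are left empty when not measured; cold_environment is true/false.",
  "fields": {
    "ambulatory": {"type": "ternary", "meaning": "walks on command"},
    "spontaneous_breathing": {"type": "ternary", "meaning": "breathing without intervention"},
    "breathing_after_airway_positioning": {"type": "ternary", "meaning": "breathing resumed after airway positioning; yes only valid when spontaneous_breathing is no"},
    "airway_positioning_attempts": {"type": "integer", "range": [0, 2], "meaning": "positioning attempts made; > 0 only valid when spontaneous_breathing is no"},
    "respiratory_rate": {"type": "number", "unit": "breaths/min", "minimum": 0},
    "respiratory_distress": {"type": "ternary", "meaning": "qualitatively compromised breathing (dyspnea, wheeze, apneic episodes)"},
    "radial_pulse_palpable": {"type": "ternary"},
    "capillary_refill_seconds": {"type": "number", "unit": "s", "minimum": 0},
    "heart_rate": {"type": "number", "unit": "beats/min", "minimum": 0},
    "follows_commands": {"type": "ternary", "meaning": "responds to a simple verbal command"},
    "purposeful_movement": {"type": "ternary"},
    "gcs": {"type": "integer", "range": [3, 15], "meaning": "Glasgow Coma Scale"},
    "major_external_hemorrhage": {"type": "ternary"},
    "hemorrhage_controlled_after_intervention": {"type": "ternary", "meaning": "bleeding controlled after a control attempt; read only downstream of a positive hemorrhage finding"},
    "obvious_death_signs": {"type": "ternary", "meaning": "decapitation / destruction of the torso"},
    "cold_environment": {"type": "boolean", "meaning": "cold conditions switch the perfusion proxy in START and the Triage Sieve"},
    "survivable_given_resources": {"type": "ternary", "meaning": "judged survivable with currently available resources (SALT expectant gate)"},
    "can_wave": {"type": "ternary", "meaning": "able to wave / respond with a purposeful movement (SALT global sorting)"},
    "minor_injuries_only": {"type": "ternary", "meaning": "apparent injuries are minor only (SALT minimal/delayed split)"}
  }
}
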