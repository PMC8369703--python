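# Sort Assess Lifesaving Intervention Triage/Transport (SALT).  The walking
# step is "global sorting": it orders who is assessed first (still -> waving
# -> walking) and never assigns a tier, so every casualty traverses this
# individual tree.  Lifesaving interventions (hemorrhage control, airway
# opening, chest decompression, antidote autoinjectors) precede assessment.
# IMMEDIATE casualties judged unsurvivable with current resources become
# EXPECTANT/GRAY.  Tier split between minimal and delayed is by whether the
# casualty has minor injuries only.
id: SALT
name: Sort Assess Lifesaving Intervention Triage/Transport (SALT)
tiers:
  - P3_DELAYED_GREEN
  - P2_URGENT_YELLOW
  - P1_IMMEDIATE_RED
  - PX_DEAD_BLACK
  - GRAY_EXPECTANT
global_sorting: true
options: {}
# antidote autoinjectors are part of SALT's LSI stage but situational (CBRN),
# so they appear in the inventory without a dedicated tree node
extra_lsi_inventory:
  - {kind: antidote_autoinjector}
root: hemorrhage_present
nodes:
  - id: hemorrhage_present
    predicate: {name: ask, field: major_external_hemorrhage}
    on_yes: {node: hemorrhage_control_attempt}
    on_no: {node: breathing}
  - id: hemorrhage_control_attempt
    # LSI stage: attempt control; assessment continues either way and the
    # persistence of the bleed is re-interrogated after the breathing check
    predicate: {name: ask, field: hemorrhage_controlled_after_intervention}
    lsi_before:
      - {kind: hemorrhage_control}
    on_yes: {node: breathing}
    on_no: {node: breathing}
  - id: breathing
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {node: hem_persistent}
    on_no: {node: airway_response}
  - id: airway_response
    predicate: {name: ask, field: breathing_after_airway_positioning}
    max_attempts: 2
    lsi_before:
      - {kind: airway_opening}
      - {kind: chest_decompression}
    on_yes: {node: hem_persistent}
    on_no: {tier: PX_DEAD_BLACK}
  - id: hem_persistent
    predicate: {name: ask, field: major_external_hemorrhage}
    on_yes: {node: hem_controlled}
    on_no: {node: commands}
  - id: hem_controlled
    predicate: {name: ask, field: hemorrhage_controlled_after_intervention}
    on_yes: {node: commands}
    on_no: {node: immediate_gate}
  - id: commands
    predicate: {name: ask, field: follows_commands}
    on_yes: {node: radial_pulse}
    on_no: {node: purposeful}
  - id: purposeful
    predicate: {name: ask, field: purposeful_movement}
    on_yes: {node: radial_pulse}
    on_no: {node: immediate_gate}
  - id: radial_pulse
    predicate: {name: ask, field: radial_pulse_palpable}
    on_yes: {node: resp_distress}
    on_no: {node: immediate_gate}
  - id: resp_distress
    predicate: {name: ask, field: respiratory_distress}
    on_yes: {node: immediate_gate}
    on_no: {node: minor_only}
  - id: immediate_gate
    # IMMEDIATE unless unsurvivable given current resources -> EXPECTANT
    predicate: {name: ask, field: survivable_given_resources}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: GRAY_EXPECTANT}
  - id: minor_only
    predicate: {name: ask, field: minor_injuries_only}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {tier: P2_URGENT_YELLOW}
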