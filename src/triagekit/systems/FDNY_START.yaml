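# Fire Department of New York modified START.  START-like flow with a
# two-sided respiratory-rate band (normal 10-30/min) and radial-pulse
# perfusion check.  The ORANGE tier is a *secondary* assessment of
# deterioration risk among GREEN/YELLOW casualties: with the enable_orange
# option set, primary GREEN/YELLOW results are flagged ORANGE_ELIGIBLE; it
# never changes the primary tier and is excluded from the criteria tally.
id: FDNY_START
name: FDNY modified START
tiers:
  - P3_DELAYED_GREEN
  - P2_URGENT_YELLOW
  - P1_IMMEDIATE_RED
  - PX_DEAD_BLACK
  - ORANGE_EXTENDED
global_sorting: false
options:
  enable_orange: false
root: walking
nodes:
  - id: walking
    predicate: {name: ask, field: ambulatory}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {node: obvious_death}
  - id: obvious_death
    # decapitation / destruction of the torso -> dead without further assessment
    # (provisional attribution, see canonical_map.yaml)
    predicate: {name: ask, field: obvious_death_signs}
    on_yes: {tier: PX_DEAD_BLACK}
    on_no: {node: breathing}
  - id: breathing
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {node: resp_rate}
    on_no: {node: airway_response}
  - id: airway_response
    predicate: {name: ask, field: breathing_after_airway_positioning}
    max_attempts: 2
    lsi_before:
      - {kind: airway_opening}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: PX_DEAD_BLACK}
  - id: resp_rate
    # abnormal: RR < 10 or > 30/min
    predicate: {name: rr_outside, normal_min: 10, normal_max: 30}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: radial_pulse}
  - id: radial_pulse
    predicate: {name: ask, field: radial_pulse_palpable}
    on_yes: {node: commands}
    on_no: {tier: P1_IMMEDIATE_RED}
  - id: commands
    predicate: {name: ask, field: follows_commands}
    on_yes: {tier: P2_URGENT_YELLOW}
    on_no: {tier: P1_IMMEDIATE_RED}
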