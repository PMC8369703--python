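# Simple Triage And Rapid Transport (START), counted as one system with its
# modified form (mSTART).  The only difference is the perfusion proxy: START
# times capillary refill (Blanch test) except in cold conditions, where the
# radial pulse is palpated instead; mSTART always palpates the radial pulse
# (set the always_radial_pulse option).
id: START_mSTART
name: Simple Triage And Rapid Transport (START/mSTART)
tiers: [P3_DELAYED_GREEN, P2_URGENT_YELLOW, P1_IMMEDIATE_RED, PX_DEAD_BLACK]
global_sorting: false
options:
  always_radial_pulse: false
root: walking
nodes:
  - id: walking
    predicate: {name: ask, field: ambulatory}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {node: breathing}
  - id: breathing
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {node: resp_rate}
    on_no: {node: airway_response}
  - id: airway_response
    # 1-2 attempts at positioning the airway before declaring the casualty dead;
    # a casualty who starts breathing only after positioning is IMMEDIATE.
    predicate: {name: ask, field: breathing_after_airway_positioning}
    max_attempts: 2
    lsi_before:
      - {kind: airway_positioning}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: PX_DEAD_BLACK}
  - id: resp_rate
    # abnormal: RR > 30/min (no lower limit in START)
    predicate: {name: rr_outside, normal_max: 30}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: perfusion_mode}
  - id: perfusion_mode
    # environment switch, not a clinical criterion: cold conditions (or the
    # mSTART variant flag) select radial pulse over capillary refill
    predicate: {name: cold_conditions, or_option: always_radial_pulse}
    on_yes: {node: radial_pulse}
    on_no: {node: cap_refill}
  - id: cap_refill
    predicate: {name: cap_refill_gt, threshold: 2}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: commands}
  - id: radial_pulse
    predicate: {name: ask, field: radial_pulse_palpable}
    on_yes: {node: commands}
    on_no: {tier: P1_IMMEDIATE_RED}
  - id: commands
    predicate: {name: ask, field: follows_commands}
    on_yes: {tier: P2_URGENT_YELLOW}
    on_no: {tier: P1_IMMEDIATE_RED}
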