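# Amberg-Schwandorf Algorithm for Primary Triage (ASAV).  Assesses breathing
# difficulties (respiratory distress) rather than counting a rate, asks for
# major external bleeding with a control attempt as lifesaving intervention,
# then radial pulse and command-following.  The "keeping airway open" LSI is
# airway maintenance on breathing casualties; the not-breathing casualty is
# declared dead without positioning attempts.
id: ASAV
name: Amberg-Schwandorf Algorithm for Primary Triage (ASAV)
tiers: [P3_DELAYED_GREEN, P2_URGENT_YELLOW, P1_IMMEDIATE_RED, PX_DEAD_BLACK]
global_sorting: false
options: {}
root: walking
nodes:
  - id: walking
    predicate: {name: ask, field: ambulatory}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {node: breathing}
  - id: breathing
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {node: resp_distress}
    on_no: {tier: PX_DEAD_BLACK}
  - id: resp_distress
    predicate: {name: ask, field: respiratory_distress}
    lsi_before:
      - {kind: airway_positioning}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: hemorrhage}
  - id: hemorrhage
    predicate: {name: ask, field: major_external_hemorrhage}
    on_yes: {node: hemorrhage_control}
    on_no: {node: radial_pulse}
  - id: hemorrhage_control
    predicate: {name: ask, field: hemorrhage_controlled_after_intervention}
    lsi_before:
      - {kind: hemorrhage_control}
    on_yes: {node: radial_pulse}
    on_no: {tier: P1_IMMEDIATE_RED}
  - id: radial_pulse
    predicate: {name: ask, field: radial_pulse_palpable}
    on_yes: {node: commands}
    on_no: {tier: P1_IMMEDIATE_RED}
  - id: commands
    predicate: {name: ask, field: follows_commands}
    on_yes: {tier: P2_URGENT_YELLOW}
    on_no: {tier: P1_IMMEDIATE_RED}
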