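# CareFlight Triage.  Three questions after the walking filter: obeys
# commands, breathing with an open airway, radial pulse.  The only route to
# the dead tier runs through a casualty unable to obey commands who is not
# breathing with an open airway.  No lifesaving interventions.
id: CFT
name: CareFlight Triage (CFT)
tiers: [P3_DELAYED_GREEN, P2_URGENT_YELLOW, P1_IMMEDIATE_RED, PX_DEAD_BLACK]
global_sorting: false
options: {}
root: walking
nodes:
  - id: walking
    predicate: {name: ask, field: ambulatory}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {node: commands}
  - id: commands
    predicate: {name: ask, field: follows_commands}
    on_yes: {node: radial_pulse}
    on_no: {node: breathing_open_airway}
  - id: breathing_open_airway
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: PX_DEAD_BLACK}
  - id: radial_pulse
    predicate: {name: ask, field: radial_pulse_palpable}
    on_yes: {tier: P2_URGENT_YELLOW}
    on_no: {tier: P1_IMMEDIATE_RED}
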