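# Modified Physiological Triage Tool.  Physiological cut-offs: respiratory
# rate abnormal when >= 22 or < 12/min (normal band 12-21 inclusive), heart
# rate >= 100/min, GCS < 14.  No lifesaving interventions.
id: MPTT
name: Modified Physiological Triage Tool (MPTT)
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
    on_yes: {node: resp_rate}
    on_no: {tier: PX_DEAD_BLACK}
  - id: resp_rate
    # abnormal: RR >= 22 or < 12/min
    predicate: {name: rr_outside, normal_min: 12, normal_max: 21}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: heart_rate}
  - id: heart_rate
    predicate: {name: hr_ge, threshold: 100}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: gcs}
  - id: gcs
    predicate: {name: gcs_lt, threshold: 14}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: P2_URGENT_YELLOW}
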