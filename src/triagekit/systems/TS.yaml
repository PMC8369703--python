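# Triage Sieve (TS), counted as one system across its evolution: capillary
# refill is the perfusion proxy, substituted by heart rate (> 120/min) in
# cold conditions.  Respiratory rate abnormal when > 29 or < 10/min (normal
# band 10-29 inclusive).  No lifesaving interventions.
id: TS
name: Triage Sieve (TS)
tiers: [P3_DELAYED_GREEN, P2_URGENT_YELLOW, P1_IMMEDIATE_RED, PX_DEAD_BLACK]
global_sorting: false
options: {}
root: walking
nodes:
  - id: walking
    predicate: {name: ask, field: ambulatory}
    on_yes: {tier: P3_DELAYED_GREEN}
    on_no: {node: obvious_death}
  - id: obvious_death
    # catastrophic, unsurvivable injury (provisional attribution,
    # see canonical_map.yaml)
    predicate: {name: ask, field: obvious_death_signs}
    on_yes: {tier: PX_DEAD_BLACK}
    on_no: {node: breathing}
  - id: breathing
    predicate: {name: ask, field: spontaneous_breathing}
    on_yes: {node: resp_rate}
    on_no: {tier: PX_DEAD_BLACK}
  - id: resp_rate
    # abnormal: RR > 29 or < 10/min
    predicate: {name: rr_outside, normal_min: 10, normal_max: 29}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {node: perfusion_mode}
  - id: perfusion_mode
    # environment switch: heart rate replaces the Blanch test in the cold
    predicate: {name: cold_conditions}
    on_yes: {node: heart_rate}
    on_no: {node: cap_refill}
  - id: cap_refill
    predicate: {name: cap_refill_gt, threshold: 2}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: P2_URGENT_YELLOW}
  - id: heart_rate
    predicate: {name: hr_gt, threshold: 120}
    on_yes: {tier: P1_IMMEDIATE_RED}
    on_no: {tier: P2_URGENT_YELLOW}
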