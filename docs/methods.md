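# Methods

## Scope and model

`triagekit` models *primary* prehospital triage only: one pass over each
casualty at the scene, no deterioration over time, no re-triage at the
collecting area, no resource or transport modelling. Each triage system is a
binary decision tree over a casualty assessment record. Trees are total and
deterministic over complete assessments: every node has a yes- and a
no-branch, every path terminates in a tier, and acyclicity is validated on
load. Tier vocabulary is Delayed/Green (P3), Urgent/Yellow (P2),
Immediate/Red (P1) and Dead/Black (PX), extended by ORANGE (FDNY-START
secondary deterioration-risk assessment) and EXPECTANT/GRAY (SALT).

Predicates are named tests with thresholds as data (`rr_outside(10, 30)`,
`cap_refill_gt(2)`, `hr_ge(100)`, `gcs_lt(14)`, …), so a reviewer can audit
a system by reading its YAML rule file rather than code.

### Encoding decisions for individual systems

- **START/mSTART** is one system; a `cold_conditions` switch selects the
  radial pulse over capillary refill in the cold, and the
  `always_radial_pulse` option gives mSTART behavior. The Triage Sieve
  substitutes heart rate (> 120/min) for capillary refill in the cold.
- **SALT's walking step is global sorting**, an assessment-ordering hint
  (still → waving → walking), never a tier assignment; every casualty
  traverses SALT's individual tree (`salt_global_sort` returns the order).
  SALT's minimal/delayed split needs a "minor injuries only" finding, which
  is therefore part of the assessment record.
- **FDNY ORANGE** is a post-pass flag (`ORANGE_ELIGIBLE`) on P2/P3 results,
  disabled by default, because it is a secondary assessment; it never
  changes the primary tier and is excluded from the criteria tally.
- **Respiratory-rate bands are inclusive-normal**: abnormal iff rate <
  lower bound or > upper bound. In the consensus band [10, 30], rates 10
  and 30 are normal, 9 and 31 abnormal (boundary-tested).
- SALT re-interrogates the hemorrhage findings after the breathing check;
  the duplicate trace entries are deliberate, keeping the tree stateless.
- A casualty who resumes breathing only after airway positioning is tiered
  Immediate in START/FDNY-START and in the modified/CBRN consensus
  variants; in SALT they continue through the combined assessment.

### Missing findings

A `Ternary` (`yes`/`no`/`unknown`) distinguishes a negative finding from an
absent observation. Tree evaluation treats `unknown` as an error naming the
criterion, because the encoded systems assume a complete bedside
assessment. An explicit opt-in (`impute_safer=True`) instead takes the
branch whose reachable outcome has the higher treatment priority (P1 > P2 >
P3, with PX and GRAY ranked lowest for this purpose, since imputing death
would be the opposite of safe), biasing ambiguity toward over-triage rather
than under-triage; results are flagged `IMPUTED`. `completeness_check`
explores both branches of unknown nodes, so an empty result guarantees
evaluation cannot fail.

## The meta-synthesis

The rephrasing/merging of per-system wording into canonical criteria was a
human content-analysis step in the source methodology; automating it would
invent data. It therefore ships as a reviewed file
(`data/canonical_map.yaml`) mapping each canonical criterion to the
(system, node) pairs that express it. The tally counts distinct member
systems over a fixed denominator of seven. A coverage check requires every
node of every system's tree to be mapped (or declared structural, e.g. the
cold-environment switches), so a fixture edit cannot silently escape the
tally. Attributions that the published tables state only as fractions
without naming contributors are marked `provisional` in the map; all of
them are minority criteria (≤ 2/7) and can never reach the majority
threshold, so the consensus derivation is invariant to them. Two printed
fractions disagree between table and running text (radial pulse 5/7 vs 4/7;
command-following "unable" 5/7 vs 4/7); the fixtures realize the table's
value and the tests assert membership in the printed range, which leaves
the ≥ 4/7 consensus unchanged either way.

The majority rule keeps criteria with fraction ≥ threshold (default 4/7),
grouped per tier and ordered airway → breathing → circulation → disability,
matching the ATLS-style derivation-table row order. Raising the threshold
can only shrink the selection (monotonicity is property-tested). The
respiratory-rate band is derived by the full-coverage rule: lower bound =
minimum of the finite per-system lower bounds (a system without a lower
limit is non-constraining), upper bound = maximum of the upper bounds; the
operation is idempotent and order-independent.

### Variants

The *majority* variant is the strict ≥ 4/7 product: not-breathing goes
directly to PX (airway positioning is only 3/7) and no LSI is enabled. The
*modified* variant applies the discussion-level amendments: respiratory
distress (a binary quality-of-breathing question) replaces rate counting;
"major external bleeding?" with a hemorrhage-control intervention is asked
before the pulse check, and a positive answer tiers the casualty Immediate
directly (field intervention plus immediate evacuation); 1–2 airway
positioning attempts precede PX; airway positioning, hemorrhage control and
antidote autoinjectors are enabled. The *CBRN* variant additionally removes
radial-pulse palpation (infeasible in hazmat gloves) while keeping the
bleeding, distress and command questions. Variants derive only from the
majority base; deriving a variant of a variant is an error.

Rescuer capability gates only the *recommendation*: an intervention whose
training or equipment requirement exceeds the rescuer's profile is traced
as "indicated, not performed", and the assigned tier never depends on the
rescuer. Training requirements default to: positioning an airway and
controlling external bleeding — layperson; judging an opened airway and
indicating antidotes — medical; field chest decompression — advanced.

Every consensus specification compiles to the same rule-file schema as the
seven source systems and runs on the generic engine; the test suite proves
the compiled tree equal to the direct implementation over an exhaustive
enumeration, and both against independently written flat-conditional
oracles.

## Synthetic cohorts and what they do (not) show

The generator draws each casualty from five latent severity classes with
default probabilities minor 0.45, moderate 0.25, severe 0.15, critical
0.10, unsalvageable 0.05 (each ≥ 0.05 so every tier is populated), mapped
deterministically to reference tiers P3 / P2 / P1 / P1 / PX. Vitals are
truncated-normal (respiratory rate with tachypneic/bradypneic mixture
components in the severe and critical classes; classes and their
location/scale parameters are in `cohort.DEFAULT_CLASS_PARAMS`), binary
findings are Bernoulli with class-specific probabilities, and fields are
kept mutually consistent: only unsalvageable casualties are apneic, walkers
follow commands, perfusion proxies (radial pulse and capillary refill)
agree, command-following implies waving ability. Cold environment is an
independent Bernoulli (default 0.2). All draws come from one
`numpy.random.default_rng(seed)`, giving exact cross-platform determinism.

The reference standard is *synthetic*: the field has no gold standard for
primary-triage correctness, so under-/over-triage rates measured here
quantify agreement between an algorithm and this generator's assumptions,
not clinical accuracy. The generator also omits real-data features —
deterioration over time, measurement error by stressed rescuers, correlated
multi-casualty mechanisms, pediatric physiology — so passing benchmarks
demonstrate engine correctness and internal consistency, not field
performance.

Mis-triage rates are computed over *rankable* casualties: reference and
assigned tier both on the ordered P3 < P2 < P1 scale. Casualties with
reference PX or assignment PX/GRAY stay in the confusion matrix but not in
the rates, because the direction of mis-triaging a dead or expectant
casualty is undefined. For agreement and sensitivity/specificity the
extended tiers fold onto core tiers (GRAY → P1, as a subset of Immediate
casualties; ORANGE → P2). Cohen's κ uses the four core tiers; in the
degenerate case of two constant columns (chance agreement 1, κ undefined)
it is reported as 1.0 under perfect raw agreement and 0.0 otherwise.

## Numerical and testing choices

- Fractions are exact (`fractions.Fraction`); no floating-point thresholds
  in the majority rule.
- Oracle-equivalence tests enumerate each tree only over the fields it
  interrogates, with numeric grids spanning both sides of every shipped
  threshold (RR grid 5…35 around 10/12/21/29/30; HR around 100 and 120;
  capillary refill around 2 s; GCS around 14) — roughly 9,000 evaluations
  per route, a few seconds in total. Acceptance-level cohort checks use
  n = 1,000 (n = 10,000 for generator frequency bounds), sized to keep the
  default suite under a few seconds while leaving binomial standard errors
  small.
- Safer-branch imputation breaks ties toward the yes-branch.
- Performance CSVs store rates via `repr` so re-reading reproduces them to
  full float precision.

## Known limitations

- The per-system trees were reconstructed from the published thresholds,
  derivation tables and prose, not from the original agencies' flowcharts;
  node-level details that the publication does not pin down (and the
  provisional attributions in the canonical map) follow this package's
  documented conventions. The tally reproducing the published sevenths is
  the correctness anchor.
- The modified/CBRN variant trees realize the discussion's explicit
  statements; where the discussion leaves a branch open (e.g. whether rate
  counting survives alongside the distress question) this package replaces
  rather than duplicates, as argued in the quality-vs-quantity passage.
- No pediatric vital-sign ranges; no secondary or hospital triage; no
  resource-dependent tiering (the two systems built that way are outside
  the encoded set by design).
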