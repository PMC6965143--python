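# Methods

## Model and update semantics

`rvdbool` simulates *synchronous* Boolean networks: each variable
`a ∈ {1..N}` holds a state in {0, 1} and owns one update rule `F_a`, an
expression over variable references, NOT, n-ary AND/OR, and a
rounded-mean threshold `MAJ`. At every cycle all variables are replaced
simultaneously by their rules evaluated on the previous state. The
synchronous scheme is the one under which a single state column per
timepoint is well defined ("the value of `a` one unit of time later");
asynchronous updating is out of scope.

`MAJ(e_1..e_k)` is 1 iff `mean(e_i) ≥ 1/2` (round-half-up). The packaged
disease model only uses `MAJ` with three inputs, where the mean lies in
{0, ⅓, ⅔, 1} and a tie is impossible — `MAJ` is then exactly the 2-of-3
majority vote. The half-up convention at exactly 0.5 is therefore a
generality decision, reachable only in user models with an even input
count; it follows the common reading of "round" and is pinned by tests.

The state space is finite and the update deterministic, so every run
ends in a fixed point or a limit cycle within at most 2^N post-event
steps. The engine hashes the full state history: a state recurring with
gap 1 that persists for `steady_window` consecutive cycles is a fixed
point; a recurrence with a larger gap (outside the current run of
identical states) is a limit cycle with that period. `steady_window`
defaults to 3 — "unchanged for multiple cycles" needs an operational
cut-off and three identical consecutive states is the smallest window
that distinguishes "settled" from "momentarily repeated"; it is
configurable because the choice is a convention, not a property of the
model. The timescale is arbitrary: cycles are not hours or weeks, so
transient lengths are comparable only within a model, not to real time.

## Perturbation events

A scenario is an initial state plus timed events. `set` events overwrite
a variable once, at their timepoint, *before* the next synchronous step;
`clamp` events re-apply from their timepoint onward. Therapies in the
packaged model are plain variables with identity self-rules (`F = self`),
so a single `set` is held by the dynamics and clamping is unnecessary —
the two modes only differ for variables whose rules would overwrite
them. Attractor detection engages only from the last scheduled event
onward; otherwise a run that settles before a scheduled switch would
stop early and the switch would never fire.

## The packaged disease model

The network (24 variables: 19 biological + 5 intervention switches)
encodes the qualitative feedback structure of microvascular rarefaction
in renovascular disease: stenosis suppresses blood flow; ischemia drives
the Ang II/ET-1 axis, NADPH oxidase and oxidative stress; oxidative
stress suppresses NO and VEGF while raising angiostatin; angiostatin
plus vasoconstriction produce MV rarefaction, which deepens ischemia and
feeds back on itself; inflammation and the TGF-β → TIMP/MMP → sclerosis
→ fibrosis chain follow. The rule set is transcribed verbatim from its
source; two transcription decisions are documented:

* **Rule numbering.** The source's per-rule function subscripts drift by
  one from variable 14 onward while the per-rule headings and prose stay
  consistent with the variable list; the heading number identifies the
  target variable. The canonical tail is F14 = 8∨4, F15 = 14, F16 = 17,
  F17 = MAJ(4, 7, 15), F18 = 13, F19 = 16, F20..F24 = identity.
* **F_7 variant.** The printed oxidative-stress formula reads TGF-β
  (variable 15) where its written description names NADPH oxidase
  (variable 3). The formula is canonical; `build_rvd_model("f7-nadph")`
  swaps 15→3 so the alternative reading stays available for sensitivity
  analysis without editing the canonical rules.

Initial conditions are recorded as 22-entry positional vectors:
positions 1–17 map to variables 1–17, positions 18–22 to the
intervention switches 20–24, and the late-stage variables 18 (severe
ischemia) and 19 (fibrosis) start at 0. This is the unique mapping
consistent with all seven scenarios (the stenosis bit is on in every
disease vector; each therapy bit is on exactly in its own arm) and with
a quiescent initial kidney.

The two interventional arms switch at timepoint 25 by replacing the
*entire* state with a recorded switch vector (quiescent biological
pattern, therapy bits flipped), realized as one `set` event per
variable. A variable-level reading ("flip only the therapy bits at
t=25") was considered and rejected: by t=25 untreated disease sits in
its fixed point, where rarefaction → severe ischemia → Ang II feedback
holds the deleterious loop closed, and flipping only VEGF
administration/stenosis cannot reopen it — the full-state switch is the
reading under which the combined angioplasty + VEGF arm reaches the
healthy steady state and the interventional VEGF arm reproduces the
preventive arm's outcome, as both are expected to. A consequence worth
knowing: the t=25 switch resets disease progression by construction, so
post-switch trajectories equal the corresponding from-onset runs shifted
by 25 cycles.

There is no calibration anywhere: scenario outcomes are pure forward
simulation of the transcribed rules.

## Concordance scoring and known discrepancies

Each scenario ships with a qualitative expectation pattern
(`data/concordance.yaml`): per-variable active/inactive for exactly the
variables its narrative outcome statement covers, with a short basis
note per entry; unstated variables are excluded. The concordance score
is the matched fraction. Mismatches are *reported, never suppressed or
repaired*, because a disagreement between printed rules and narrative
claims is a finding.

Under the canonical rules the scores are: untreated 100%, ET-A blockade
100%, angioplasty + VEGF 100%, anti-oxidant ≈ 82%, simvastatin ≈ 53%,
preventive/interventional VEGF ≈ 44/56%. The persistent disagreements
are forced by the printed rules themselves, e.g.: `F_VEGF = ¬OxStress ∨
VEGFadmin`, so VEGF cannot be on under simvastatin (oxidative stress
stays active via TGF-β and no exogenous VEGF is given) although the
statin arm's claims say it activates; and under VEGF-only therapy the
`MAJ(AngII, ¬NO, Inflammation)` vasoconstriction rule stays on while
ischemia persists, so MV rarefaction remains active despite the claim
that it clears. The `f7-nadph` variant does not resolve these (NADPH
oxidase is also persistently active in those arms).

## Rule-file and scenario formats

Rule files use the "targets, factors" text dialect (`!`, `&`, `|`,
parentheses, `MAJ(...)`; precedence NOT > AND > OR) with `#%`/`#@`
metadata lines for network name, roles and groups. The writer emits a
canonical form — sorted metadata, minimal but structure-preserving
parentheses (a nested AND inside AND keeps its parentheses rather than
flattening) — and parse→write→parse is byte-stable; free-text variable
annotations are deliberately not serialized. Scenario files are YAML
with assignments by variable *name*; they are read with a
string-preserving loader because bare `NO` is a YAML 1.1 boolean. A
positional importer (`initial_vector`, event `vector`) accepts the
22-entry transcription format directly.

## Testing strategy and what it shows

The suite cross-checks the engine against independent oracles: a second,
plain-lambda transcription of the 24 rules with its own iteration loop;
pen-and-paper fixed points derived before the engine existed for all
seven scenarios; brute-force truth tables for `MAJ`; De Morgan and
determinism properties on random expression trees (hypothesis); and
exhaustive attractor checks over every start state of small random
networks (`n ≤ 6` exhaustively, 1000 networks with sizes 1–10 in the
acceptance script). Random networks are generated with bounded in-degree
(≤ 3 inputs) and shallow trees — enough to exercise every operator and
the attractor machinery, not a model of any biological ensemble.

Passing tests show the implementation faithfully simulates the
transcribed rule set; they cannot show the rule set faithfully abstracts
renal pathophysiology — the model is qualitative, uncalibrated, binary,
and blind to dose, time scale and partial activation. Limit cycles do
not occur in the packaged scenarios (asserted), but diffing is defined
only for fixed points and raises otherwise by design.
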