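# Methods

## The assessment model

The engine encodes the EWGSOP2 operational definition of sarcopenia as a
pure decision function over three three-valued stage verdicts
(`low` / `not_low` / `unknown`):

| strength | quantity | performance | grade |
|---|---|---|---|
| unknown | any | any | not_assessed |
| not_low | any | any | no_sarcopenia |
| low | not low* | any | probable_sarcopenia |
| low | low | not low* | confirmed_sarcopenia |
| low | low | low | severe_sarcopenia |

*"not low" here covers both `not_low` and `unknown`: confirmation and
severity must rest on a measured low flag, never on a missing
measurement. Symmetrically, a measured *normal* strength terminates
grading at `no_sarcopenia` even when low-quantity data exist — strength
is the diagnosis criterion, and the collected quantity values are still
reported to the clinician in the assessment record. These two choices
are the only places where the decision table is not forced by the
criteria themselves; both were genuinely open and are resolved in favour
of "a grade asserts measured evidence".

The SARC-F case-finding score is computed and reported but never gates
any stage or the grade, in either direction. Item answers are captured
as categorical difficulty levels and the falls item as a raw count,
banded by the engine (0 falls → 0, 1–3 → 1, ≥ 4 → 2), so the banding
rule itself is under test. A response with any unanswered item aborts
scoring: a partial SARC-F total is undefined and silently scoring
missing items as 0 would bias the screen toward negative.

## Stage rules and their parameters

All thresholds live in `sarcoscreen.config.Cutoffs` and are overridable
from a YAML/JSON file. Defaults:

| quantity | rule | default |
|---|---|---|
| best grip, men | low if `<` | 27 kg |
| best grip, women | low if `<` | 16 kg |
| best 5-rep sit-to-stand | low if `>` | 15 s |
| SMI, men | low if `<` | 15 kg/m² |
| SMI, women | low if `<` | 12 kg/m² |
| gait speed | low if `≤` | 0.8 m/s |
| gait course | — | 4.572 m |

Boundary semantics are strict for the first five rules — a measurement
exactly at the cut-off is *not* low, the literal reading of the `<`/`>`
statements — and tested explicitly at the boundary. The gait-speed
cut-off is the one threshold the source rubric leaves numeric-free; the
EWGSOP2-recommended ≤ 0.8 m/s (inclusive) is used and is deliberately
the most prominent configurable. The course defaults to exactly 15 ft
(4.572 m) rather than the 4.6 m gloss; it rounds to 4.6 at one decimal.

Grip sessions accept 1–3 trials per hand (more than 3 is rejected;
fewer than 3 is accepted with a logged protocol warning, since field
conditions vary); the score is the maximum force with both hands pooled.
Sit-to-stand takes 1–3 timed repetitions, scored by the minimum; the two
practice trials of the protocol are not recorded. When both strength
tests are present the stage verdict is the logical OR of the two low
flags (worst-result rule). No rounding is applied before any comparison;
reports display one decimal.

### Muscle quantity

Skinfolds are entered in mm (caliper convention) and converted to cm in
exactly one place, `corrected_girth` — the unit decision is the largest
silent-error risk in the chain, so it is centralized and tested there.
Girth/skinfold pairing: arm ↔ triceps, thigh ↔ thigh, calf ↔ calf; the
biceps skinfold is collected and stored but unused by the estimate (the
prediction model does not take it). Ethnicity defaults to the
white/Hispanic (zero) race term when unrecorded.

Two known validity caveats are surfaced in every report that
includes a quantity stage: the skeletal-muscle estimate is compared
against cut-offs derived from DXA lean mass, and the prediction model
was not developed in older adults; both can overestimate sarcopenia.
The engine implements the published pairing as specified and does not
attempt to correct for it.

## Synthetic cohorts

The generator emulates the *decision-relevant geometry* of an
older-adult screening population, not its epidemiology. Patients are
constructed stratum-first: the intended grade fixes the three stage
flags, and each measurement is sampled inside the region that produces
its flag with at least a configurable margin of clearance from the
cut-off (defaults: 2 kg grip, 2 s sit-to-stand, 0.5 kg/m² SMI,
0.15 m/s gait). Sampling regions are additionally inset by small guards
(0.06 kg, 0.06 s, 0.10 kg/m², 0.02 m/s) that absorb the recording
resolution (0.1 kg / 0.1 s / 0.1 cm and 0.1 mm / 0.01 s), so the
clearance guarantee survives rounding. This makes classifier recovery an
exact property — a seeded cohort with a 50/30/15/5 allocation is graded
back to exactly 50/30/15/5 — rather than a statistical one.

Anthropometry is back-solved: plausible baseline girths (arm 24–30,
thigh 40–52, calf 28–36 cm) are scaled by a common factor, found with
`scipy.optimize.brentq` (xtol 1e-10 on the scale factor, far below
1e-6 kg/m² on the SMI scale), so that the muscle-mass model lands on the
target SMI; circumferences are then reconstituted from the scaled girths
plus sampled skinfolds (5–18 mm). Stratum counts come from
largest-remainder rounding of n·proportions with ties broken in
canonical stratum order. Heights are Normal(1.72, 0.06) m for men and
Normal(1.60, 0.06) for women, clipped to [1.45, 1.95]; ages uniform over
the spec's range (default 65–90); SARC-F answers worsen stochastically
with stratum severity.

Randomness: one root seed; patient *i* draws from `default_rng([seed, i])`,
so substreams are independent of insertion order and equal specs produce
byte-identical CSV files.

A `realistic` mode replaces the stratum-conditional regions with
overlapping population-style distributions (grip Normal(30, 7)/
Normal(19, 7) kg by sex, sit-to-stand Normal(13, 4) s, SMI
Normal(15.5, 2.3)/Normal(13, 2.3) kg/m², gait speed Normal(0.95, 0.25)
m/s, clipped to physiological floors) for demonstrations; it carries no
allocation guarantee and leaves `intended_stratum` unset.

What passing tests on synthetic cohorts do **not** show: anything about
real measurement noise, device bias, inter-rater variability, missing
data patterns, or the true joint distribution of strength, mass and
speed in older adults. They show that the decision logic, unit handling
and I/O are exactly as documented.

## Split export

The identity/measurement separation of the deployed architecture is
emulated as two plain CSV stores joined only by a pseudonym key — an
HMAC-SHA256 of the patient id under a caller-supplied secret, truncated
to 24 hex digits. The measurement store carries no direct identifier;
the join reconstructs every field; the same secret reproduces the same
files and a different secret re-keys without touching the payload. Real
encryption, key management and regulatory machinery are explicitly out
of scope: the split is a separation *contract*, not a security
implementation.

## Numerical and degenerate-input choices

* All comparisons are performed on unrounded floats; display rounding is
  cosmetic.
* `corrected_girth` rejects non-positive results ("skinfold exceeds limb
  girth") and the error propagates through `assess_quantity`.
* Empty trial/time lists, non-positive times, negative fall counts,
  out-of-range ages/heights and malformed CSV cells are rejected with
  errors naming the offending field (and row/column for files). Batch
  assessment collects per-record failures instead of aborting.
* Boundary recovery in tests and in the acceptance script uses 80-step
  bisection of the monotone decision predicates (width ≪ 1e-9 on every
  bracket used).

## Problem sizes

The test suite and acceptance script run entirely on constructed inputs:
exhaustive enumerations (27 grading combinations, 3⁴ × 5 SARC-F
responses), 100-draw random oracles for the muscle-mass model, and
synthetic cohorts of 1–100 patients. The full suite completes in a few
seconds on one CPU.

## Known limitations

* The engine consumes completed measurements; device capture, timing UIs
  and questionnaire presentation are out of scope.
* Only the anthropometric muscle-quantity route is implemented — no
  DXA/BIA/CT/MRI ingestion, no appendicular-mass cut-offs, no
  calf-circumference-only proxy.
* Severity uses gait speed only (no SPPB, TUG or 400 m walk
  alternatives), and the Ishii screening test is not implemented.
* Grades are deterministic labels; no probabilistic grading or
  longitudinal modelling.
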