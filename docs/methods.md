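# Methods

## Model

The IPI is a Mamdani fuzzy inference system over four crisp inputs
sampled at 1 Hz: PetCO₂ (mmHg), RR (breaths/min), SpO₂ (%) and PR
(beats/min). Scoring a sample proceeds in five steps:

1. **Fuzzification.** Each input is clamped to its physical range and
   mapped to membership grades over its labelled sets — VL, L, N, H, VH
   for PetCO₂ and RR; L, N, H for SpO₂ and PR. Membership functions are
   trapezoids chained so that each falling edge coincides with the next
   rising edge and the end sets are shoulders pinned to the range ends.
   This makes every partition *sum-to-one*: a crisp value splits unit
   mass between at most two adjacent labels, which is the precise
   meaning of "partial membership in the adjacent range". Non-finite
   inputs are rejected (stream scoring turns them into trace gaps);
   out-of-range values (SpO₂ > 100, negative rates) are clamped and
   flagged rather than raised, because sensor artifacts must not crash
   streaming computation.
2. **Rule evaluation.** The primary rule base has complete coverage:
   one consequent level (1–10) for each of the 5 × 5 × 3 =
   75 (RR, PetCO₂, SpO₂) label combinations. Rule activation is the
   `min` of its antecedent grades; per-level activation is the `max`
   over rules sharing the consequent.
3. **Implication and aggregation.** Min (clipping) implication against
   symmetric triangular output sets of half-width 0.5 centred on the
   integers 1–10 of the output universe [0.5, 10.5]; aggregation is the
   pointwise `max`.
4. **Defuzzification.** Centroid of area of the aggregated curve.
   Because the output triangles have disjoint supports, the centroid is
   available in closed form: a triangle clipped at height *h* has area
   ∝ *h*(2 − *h*) and keeps its centroid at its centre *k*, so the
   result is Σ *k·h_k*(2 − *h_k*) / Σ *h_k*(2 − *h_k*). This replaces
   the 0.001-step grid integration one would otherwise use; the tests
   keep dense numerical integration as an independent oracle and agree
   to < 10⁻⁶. With all activations zero a `NoRuleFiredError` is raised
   rather than a silent default (it cannot happen under the shipped
   complete rule base). Half-width 0.5 (not 1.0) is what keeps every
   triangle inside the universe, making the centroid of an unclipped
   level-*k* set exactly *k* — hence a single crisp rule firing at 1.0
   returns its consequent exactly.
5. **Secondary PR rules and rounding.** If PR is L while PetCO₂ and RR
   are H/VH, or PR is H while PetCO₂ and RR are L/VL, one point is
   subtracted. The subtraction is graded by the fuzzy degree of the
   compound condition, min(g_PR, max g_PetCO₂, max g_RR), rather than a
   crisp step: at fully crisp grades it is exactly "subtract one", and
   in between it preserves continuity of the score in its inputs. The
   result is floored at 1, then rounded half-up to the reported integer;
   the continuous pre-rounding value is exposed alongside.

The algorithm is deliberately non-adaptive: no temporal smoothing,
trend handling or per-patient baseline. The stream scorer is therefore
stateless and splitting/concatenating a recording leaves the trace
unchanged.

## Calibration of the shipped defaults

Exact breakpoints and rule-table cells were never published (the rule
figures are images, with only a handful of cells quoted in text), so
the shipped defaults are a constrained reconstruction, not a
transcription. The constraints:

* anchors — (RR 12, PetCO₂ 26, SpO₂ 98, PR 70) → 8;
  the same at SpO₂ 90 → 5; all-normal → 10; apneic/hypoxic extremes
  → 1; the quoted rule (PetCO₂ VH, RR VH, SpO₂ N) → 2;
* SpO₂ 98 fully N, SpO₂ 85 fully L, RR 12 fully N, RR 0 fully VL;
* monotonicity — within each matrix, moving away from the (N, N) cell
  never raises the consequent, and the low-SpO₂ matrix is cell-wise ≤
  the normal-SpO₂ matrix (desaturation never raises the score).

Adult partitions (breakpoints a, b, c, d; plateau [b, c]):

| channel | VL | L | N | H | VH |
| --- | --- | --- | --- | --- | --- |
| PetCO₂ | 0,0,12,20 | 12,20,30,35 | 30,35,45,50 | 45,50,60,70 | 60,70,150,150 |
| RR | 0,0,4,6 | 4,6,9,11 | 9,11,20,25 | 20,25,30,35 | 30,35,60,60 |
| SpO₂ | — | 0,0,85,94 | 85,94,99.5,100 | 99.5,100,100,100 | — |
| PR | — | 0,0,45,55 | 45,55,100,120 | 100,120,250,250 | — |

Pediatric modes keep PetCO₂/SpO₂ and the rule matrices and shift only
the RR/PR plateaus per standard pediatric reference ranges (e.g. RR N
plateau 22–34 at 1–3 y, 20–32 at 3–6 y, 17–28 at 6–12 y; PR N plateau
90–150, 80–140, 70–120). All values are config-overridable via
YAML/JSON files whose SHA-256 checksum is logged on every run.

Consequent matrices (rows RR VL→VH, columns PetCO₂ VL→VH):

```
SpO2 N (and H):            SpO2 L:
1  2  3  2  1              1  1  1  1  1
3  5  6  5  3              1  2  3  2  1
6  8 10  8  6              2  2  3  2  2
4  6  8  6  4              1  2  3  2  1
2  3  5  3  2              1  1  2  1  1
```

SpO₂ has no physiologically meaningful "high" deficit, but the model
keeps three sets for the channel; H occupies a narrow shoulder
(99.5–100 %) whose consequents equal the N layer, so a saturation of
100 % scores identically to 98 %.

## Monotonicity: what holds, and a known artifact

* All-normal inputs score exactly 10, and moving any single parameter
  away from its normal plateau (others held normal) never raises the
  continuous score.
* Holding RR, PetCO₂ and PR at any *crisp* label values, the score is
  non-increasing as SpO₂ falls from 100 to 70 — the behaviour the rule
  tables describe.
* With RR or PetCO₂ fixed *mid-transition* between labels, min/max
  aggregation admits a small non-monotone wiggle along the SpO₂ sweep
  (observed < 0.05 IPI points, tested as a bound). The cause is
  structural: a level fed by both SpO₂ layers has activation
  min(h_cell, max(g_N, g_L)), and max(g_N, g_L) dips to 0.5 mid-
  transition in any sum-to-one partition, momentarily shifting weight
  toward minority cells. No consequent-matrix choice removes it while
  the floor cells (consequent 1) exist in both layers. The same
  mechanism exists in the narrow N→H SpO₂ shoulder; it is invisible at
  the 0.5-step sweep grid and bounded by the same analysis.

## Event detection

Conditions are evaluated per grid second exactly as printed (≤ 85
inclusive; < 90, < 8, > 50 strict; RR 8–12 inclusive), except that
"PetCO₂ = 0" and "RR = 0" are tested as `< 1` to guard against sensor
quantization and CSV float round-trips. Events are maximal runs meeting
the kind's minimum duration, with no bridging: a single interrupted or
invalid second splits a run, because the definitions say "for at least
N s" with no merge rule. One episode may yield several kinds (a 40-s
apnea is both severe and clinically significant; any SpO₂ < 90 run also
counts as hypoxia even when a more specific hypoventilation pattern
co-occurs) — the epoch-based analysis counts overlap harmlessly.

## Reliability analysis

Epochs are 60 s with 15 s overlap, read as stride 45 s (the stride-15
reading is exposed as an option). An epoch is positive for a class if
it has any time overlap with an event of that class — an event clipped
at an epoch edge still reflects patient state within the epoch. Epochs
containing invalid seconds are excluded and reported. Counts are pooled
across streams before computing sensitivity and specificity; the ROC
uses thresholds 1–9 with anchors (0,0) and (1,1) and trapezoidal AUC.
Zero denominators raise `UndefinedMetricError` instead of returning 0.
The permutation null shuffles clinical labels across pooled epochs,
preserving both margins; its AUC distribution centres on 0.5.

## Synthetic generator and what a green test establishes

Channels are constant baselines (inside the normal plateaus of the
chosen mode) plus Gaussian noise, clamped to physical range. Default
SDs (PetCO₂ 1.5 mmHg, RR 0.8, SpO₂ 0.6, PR 2.0) keep baselines ≥ 7σ
away from every event threshold, so ground truth is unambiguous.
Episodes override the relevant channels with constant values satisfying
their condition with margin (e.g. non-bradypneic hypoventilation:
PetCO₂ 25, RR 10, SpO₂ 87); optional linear ramps flank episodes and
are excluded from ground truth, so detected events may extend into
ramps but always contain the scripted interval. One seed spawns four
independent per-channel substreams, so adding an episode on one channel
never reshuffles another. The standard benchmark is 20 × 30-min adult
streams: 5 event-free controls and 15 streams with two episodes each
(every kind occurring 6 times, census in the manifest); benchmark
episodes use ramp 0 so detector output equals ground truth exactly.

The generator emulates threshold semantics only: no SpO₂ lag behind
ventilation, no cardiorespiratory coupling, no motion artifact or
cannula dislodgement. A green end-to-end test therefore establishes
that the pipeline is self-consistent (scripted compromise drives the
score to its floor and the epoch analysis recovers it with sensitivity
1.0 and near-perfect specificity); it does not establish clinical
sensitivity/specificity, which would require real recordings where
events and artifacts are entangled.

## Numerical choices

* Rounding: half-up on the adjusted continuous score, clamped to
  [1, 10].
* Resampling on CSV read: nearest neighbour onto the 1 Hz grid with a
  ≤ 1 s tolerance; farther gaps become invalid seconds (trace gaps).
* Defuzzification: exact closed form (above); tests compare against
  dense trapezoidal integration at ~10⁻⁵ step.
* Intervals are half-open `[start, end)` in integer seconds throughout.
* Determinism: every stochastic component takes an explicit seed;
  identical seeds give bit-identical streams, traces and reports.

## Limitations

* The calibration is a reconstruction satisfying the published anchors
  and monotonicity structure; cells far from the anchors are plausible
  rather than authoritative, and scores there may differ from the
  commercial implementation.
* Scoring below age 1 is undefined and unsupported.
* The mid-transition SpO₂ wiggle described above.
* No artifact rejection: a dislodged sampling cannula is
  indistinguishable from true apnea at this layer.
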