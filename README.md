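# ipindex — Integrated Pulmonary Index toolkit

Continuous respiratory monitoring produces four parallel channels —
end-tidal CO₂ (PetCO₂, mmHg), respiration rate (RR, breaths/min), oxygen
saturation (SpO₂, %) and pulse rate (PR, beats/min) — that are routine
reading for anesthesiologists but hard to integrate at the bedside on a
general ward. The **Integrated Pulmonary Index (IPI)** compresses them
into a single score from 1 (*immediate intervention required*) to 10
(*normal, no action required*) using Mamdani fuzzy inference, so that a
deteriorating patient shows up as a falling single digit rather than
four drifting waveforms.

`ipindex` is a self-contained reimplementation of that algorithm for
offline analysis and simulation:

* **Fuzzy scoring engine** — trapezoidal membership partitions
  (PetCO₂/RR: VL·L·N·H·VH; SpO₂/PR: L·N·H), a complete
  RR × PetCO₂ × SpO₂ rule base, `min` for AND, `max` for aggregation,
  centroid-of-area defuzzification, and the secondary pulse-rate rules
  (low PR with high PetCO₂+RR, or high PR with low PetCO₂+RR, subtracts
  one point). Adult plus three pediatric modes (1–3, 3–6, 6–12 y).
* **Event detection** — severe events (apnea: PetCO₂ = 0 ∧ RR = 0 for
  ≥ 30 s; hypoxia: SpO₂ ≤ 85 % for ≥ 15 s) and clinically significant
  events (apnea ≥ 15 s; bradypneic hypoventilation with hypoxia:
  PetCO₂ > 50 ∧ RR < 8 ∧ SpO₂ < 90; non-bradypneic hypoventilation
  with hypoxia: PetCO₂ < 30 ∧ RR 8–12 ∧ SpO₂ < 90; hypoxia:
  SpO₂ < 90 %), plus IPI events (IPI ≤ threshold for ≥ 15 s).
* **Reliability analysis** — 1-min epochs overlapping by 15 s, pooled
  TP/FP/FN/TN per IPI threshold, sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP), ROC/AUC, and a permutation null.
* **Synthetic vitals** — a seeded generator of 1 Hz streams with
  scripted compromise episodes and exact ground truth, including a
  standard 20 × 30-min benchmark, so the whole pipeline is testable
  without clinical recordings.

## Worked example

The calibrated defaults reproduce the published step-by-step example:
RR 12 bpm with PetCO₂ 26 mmHg (hypocapnic hypoventilation) under normal
SpO₂/PR scores 8; dropping SpO₂ to 90 % pulls the score to 5.

```python
from ipindex import VitalSample, compute_ipi

for spo2 in (98, 90):
    res = compute_ipi(VitalSample(t=0, etco2=26, rr=12, spo2=spo2, pr=70))
    print(f"SpO2={spo2}%  IPI={res.ipi}  (raw {res.ipi_raw:.3f})")
```

```
SpO2=98%  IPI=8  (raw 8.000)
SpO2=90%  IPI=5  (raw 5.223)
```

At SpO₂ 98 % the sample is crisp (RR fully N, PetCO₂ fully L), so the
centroid lands exactly on the rule-table cell 8. At 90 % the sample has
partial membership in low SpO₂; the low-SpO₂ rule layer fires alongside
and the aggregated centroid (5.223) rounds to 5. PR 70 is fully normal,
so no secondary subtraction applies.

## Command line

```bash
ipindex simulate --seed 7 --out-dir demo --single --duration 300 --episode apnea:100:40
ipindex compute demo/stream_00.csv -o demo/trace.csv
ipindex detect-events demo/stream_00.csv -o demo/events.csv
ipindex validate --seed 0 --thresholds 3,4,5,6 --event-class severe \
    -o demo/report.json --permutations 100
```

The 40-s scripted apnea is reported as both a severe and a clinically
significant apnea (`events.csv`: `severe_apnea,100,140,40` and
`cs_apnea,100,140,40`), the IPI trace sits at 1 throughout it, and the
benchmark validation report shows sensitivity 1.0 for severe events at
every threshold 3–6 (e.g. threshold 3: TP 24, FN 0, specificity 0.984)
with a permutation-null AUC of ≈ 0.5.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch on the shipped adult calibration: the two
worked-example scores (`t1`, `t2`), and the maximum (`t3`) and minimum
(`t4`) rounded IPI over an exhaustive step-1 grid of physically valid
inputs (PetCO₂ 0–100 mmHg × RR 0–60 × SpO₂ 70–100 % × PR 30–180 bpm,
≈ 28.8 M combinations), writing one JSON object per target.

## Layout

| module | contents |
| --- | --- |
| `ipindex.fuzzy` | generic trapezoid/partition/rule/centroid machinery |
| `ipindex.engine` | calibrated IPI model, modes, batch/stream scoring |
| `ipindex.events` | clinical and IPI event detectors |
| `ipindex.reliability` | epochs, truth tables, ROC/AUC, permutation null |
| `ipindex.synthetic` | seeded stream generator + standard benchmark |
| `ipindex.io`, `ipindex.cli` | CSV/YAML dialects and the `ipindex` CLI |

See `docs/methods.md` for the model description, calibration rationale,
numerical choices and known limitations.
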