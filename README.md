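# mechwork

Mechanical work from whole-body kinematics as a workload metric for
on-court tennis, validated against acute neuromuscular fatigue.

## The problem

Workload monitoring in tennis mostly relies on session counts, hitting
volume, or distance/velocity zones — none of which capture the mechanical
demand of the constant accelerations and decelerations the sport imposes.
Markerless motion capture makes a biomechanical alternative practical:
**mechanical work** accumulated by a player, split into

- **external work** `W_ext` — work done to accelerate and raise the
  whole-body centre of mass (CoM): the sum of increments (positive work)
  and decrements (negative work) of the CoM energy series
  `E(t) = ½|v(t)|² + g·h(t)` (J/kg, mass-normalised);
- **internal work** `W_int` — work done to accelerate segments relative to
  the CoM: per segment `½m|v_rel|²/M + ½ωᵀIω/M`, summed within limbs
  (bilateral legs, bilateral arms, trunk), with limb-level increments
  summed across limbs;
- **total work** `W_tot = W_ext + W_int`;

plus two cheaper CoM surrogates: the **pelvis origin** and a
**bounding-box pseudo-CoM** (least-squares intersection of the rays
back-projected through per-camera bounding-box centres).

The package implements the complete analysis chain for a standardised
on-court fatiguing protocol (cycles of three serve+groundstroke sets, the
third followed by a maximal sprint to the net): zero-lag Butterworth
filtering with residual-analysis cutoff selection, protocol event
detection (serve start from the vertical CoM countermovement, change of
direction into the sprint, 8.5 m sprint crossing), work bookkeeping per
section, per-player Pearson correlation of peak sprint velocity (% of
maximum — the fatigue measure) against cumulative positive work, Fisher-z
random-effects pooling across players with 95% CI (DerSimonian–Laird),
magnitude labels (large / very large / extremely large at |r| > 0.5 / 0.7 /
0.9), and repeated-measures Bland–Altman agreement between the proxies and
the true external work.

Because raw motion-capture data of this kind is not publicly deposited,
the package ships a seeded synthetic motion generator (`mechwork.simulate`)
that emulates the protocol — 200 Hz, 30-s trials, a prominent serve peak,
eight lateral shuttles, a sprint with a fatigue-driven peak velocity
(baseline 6.0 ± 0.5 m/s), internal work near one third of total, and
proxies whose extra high-frequency motion inflates their work — with full
ground truth for validation.

## Worked example

```bash
python examples/03_cohort_fatigue_analysis.py
```

```
players: 5   cycles completed: 37

pooled correlation of peak sprint velocity (%max) vs cumulative work:
  total          r = -0.962  [-0.983, -0.915]  (extremely large)
  external       r = -0.961  [-0.983, -0.913]  (extremely large)
  pelvis         r = -0.962  [-0.983, -0.914]  (extremely large)
  bounding_box   r = -0.962  [-0.983, -0.914]  (extremely large)

proxy agreement with CoM external work (per cycle):
  pelvis         bias =  +47.8 J/kg,  LoA = +/-12.9 J/kg
  bounding_box   bias =  +77.8 J/kg,  LoA = +/-18.7 J/kg
```

The pooled `r` near −1 says that the more work a player has accumulated,
the slower their maximal sprint — mechanical work tracks acute
neuromuscular fatigue.  All four work variants carry essentially the same
signal, while the positive biases show both proxies systematically
overestimate external work: usable for monitoring one player in one
context, not for absolute comparisons.  The other examples
(`examples/01..04`) demonstrate single-trial work computation,
multi-camera triangulation with outlier rejection, and residual-analysis
cutoff selection.

A thin CLI wraps the same functions:

```bash
mechwork all --seed 1 --players 15 --out results/run1
mechwork simulate --seed 1 --players 2 --out trials/
```

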