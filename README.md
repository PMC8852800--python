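# paleogait

Planar quadrupedal gait prediction by trajectory optimization, with
fossil-trackway ichnometrics.

## The problem

Fossil trackways record where a quadruped's feet fell, but not *how* it
moved: disparate gaits can leave nearly identical print patterns.  The key
observable is the **track phase** `Φ_T = d/D` — the along-track distance
from a pes (hind) print to its ipsilateral manus (fore) print, divided by
the stride length — which is tied to the **limb phase** `φ_L` (the
hind-to-fore contact timing lag as a fraction of the stride period) through
the steady-gait relation

    Φ_T = mod(φ_L + LBx/D, 1),

where `LBx` is the horizontal glenoid-to-acetabulum distance.  If a
biomechanical model can predict which gait (which `φ_L`) is energetically
optimal at a given speed and stride, its predicted track phase can be
compared directly with fossil trackways.

`paleogait` implements both sides of that comparison for users in
comparative biomechanics and vertebrate ichnology:

- a **planar trajectory-optimization gait model** — rigid trunk, four
  massless axial legs, work-plus-force-rate objective, relaxed contact
  complementarity, half-cycle symmetry — solved by direct collocation with
  seeded multistart;
- a **trackway geometry pipeline** — digitized two-landmark footprints to
  stride vectors, manus-pes distances, track phase, dynamic-similarity
  speed estimates (`U_H' = 0.25·(D/H)^1.67`), and glenoacetabular
  estimates from slow trackways (`LBx = d + D/2`);
- a **synthetic trackway generator** with known ground truth, so the
  geometry pipeline is testable end-to-end;
- shipped reference inputs: body models for *Batrachotomus
  kupferzellensis* (a Middle Triassic crocodile-line archosaur) and a
  Belgian Malinois dog, and published summary data for 14 Triassic
  *Isochirotherium* / *Brachychirotherium* trackways.

## Worked example: trackway analysis

```python
from paleogait import BATRACHOTOMUS, summary_from_means, gad_from_trot, murphy_number

# published means for one Middle Triassic Isochirotherium trackway:
# pes 0.34 m, manus 0.12 m, manus-pes distance 0.24 m, stride 1.68 m
s = summary_from_means("12", 0.34, 0.12, 0.24, 1.68, BATRACHOTOMUS)
print(f"track phase {s.track_phase:.2f}  hip height {s.hip_height:.2f} m  "
      f"speed U_H' {s.speed:.2f}")
print(f"Murphy number {murphy_number(BATRACHOTOMUS):.2f}")
print(f"LBx from a slow trot trackway (d=0.25, D=0.91): "
      f"{gad_from_trot(0.25, 0.91):.3f} m")
```

prints

```
track phase 0.14  hip height 0.99 m  speed U_H' 0.60
Murphy number 3.04
LBx from a slow trot trackway (d=0.25, D=0.91): 0.705 m
```

The track phase (0.14) and estimated dimensionless speed (0.60) are the
trackway's coordinates on the comparison axes; the hip height scales the
*Batrachotomus* model to the trackmaker; the slow-trackway `LBx` estimate
(0.705 m) can be checked against the model's 0.74 m.

## Worked example: gait prediction

```python
from paleogait import DOG, PlanarGaitModel

model = PlanarGaitModel(DOG, U_H=0.4, c_prime=3e-3, mesh_intervals=16,
                        modulation_window=(0.0, 0.6))
result = model.fit(multistarts=4, seed=1)
print(result.summary())
```

prints

```
Planar gait optimization: Belgian Malinois dog
  U_H' = 0.400   D_H' = 1.325   c' = 3.0e-03   mesh = 16
  converged starts: 4/4
  J = 14.780 J  (work 11.139, penalty 3.641)
  cost of transport = 0.0846 (work-only 0.0638)
  limb phase = 0.202   track phase = 0.972
  duty factors: LH=0.66  RH=0.66  LF=0.66  RF=0.66
  GRF classes: LH=double-humped  RH=double-humped  LF=double-humped  RF=double-humped
  gait: lateral-sequence walk
  max defect = 3.05e-12   max complementarity = 1.00e-03
```

At this slow speed the optimizer picks a lateral-sequence walk (limb phase
near 0.25) with the double-humped, vaulting ground-reaction-force profiles
of walking; re-fitting at `U_H=1.2` yields a trot (limb phase 0.5) with
single-humped bouncing profiles.  `result.solution` carries the full state
and force time series, `result.starts` the per-start solver log, and
`paleogait.sweep(...)` maps gaits over a speed grid with transition
detection.

A command-line interface wraps the same operations:

```sh
paleogait optimize --body dog --uh 0.4 --cprime 3e-3 --seed 1 --out sol.json
paleogait sweep --body batrachotomus --uh-grid 0.25:1.1:0.1 --cprime 3e-3 --out atlas.csv
paleogait analyze-trackway landmarks.csv --body batrachotomus --out summary.csv
paleogait synth-trackway --phi-l 0.5 --stride 0.91 --lbx 0.705 --out synth.csv
```

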