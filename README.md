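# genpol

Simulation and analysis of **general compact-polarimetric (CP) SAR**
data: synthesis of arbitrary-transmit-ellipse CP observations from
quad-pol scattering matrices, the **delta-alpha/alpha target
decomposition**, speckle filtering, a ground-truth-known multi-temporal
scene simulator, and SVM-based crop classification with
transmit-ellipse sweep and phenology-curve analyses.

It is aimed at radar remote-sensing researchers who want to study how
the choice of transmit polarization affects scattering-mechanism
retrieval and crop discrimination — in particular the separation of two
rice cultivation types (transplanted hybrid, T-H, and direct-sown
japonica, D-J) across a growing season — without access to proprietary
sensor products: every input is simulated with known mechanisms, so
every result can be checked against closed forms.

## The model in brief

A compact-pol radar transmits one elliptical polarization, parameterized
by orientation θ and ellipticity χ with Jones amplitudes
a = cosθcosχ − j sinθsinχ, b = sinθcosχ + j cosθsinχ. For a, b ≠ 0 the
normalized receive channels are

    E1 = S_HH + (b/a) S_HV,    E2 = S_VV + (a/b) S_VH,

with the classic π/4 and CTLR modes as the special cases (π/4, 0) and
(0, −π/4). The decomposition extracts, from windowed second-order
statistics, a mechanism angle in [0°, 90°]

    alpha_B   = arctan((T22 + T33)/T11)              (quad-pol, from T3)
    alpha_BCP = arctan(⟨|E1−E2|²⟩ / ⟨|E1+E2|²⟩)      (compact-pol, from T2)

(0° surface, mid-range volume, 90° double bounce) and a signed
randomness parameter delta_alpha = alpha − alpha_0, where
alpha_0 = arctan(|ρ−1|²/|ρ+1|²) is the ideal angle implied by the
complex co-polar ratio ρ alone. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
import genpol as g

# canonical limits of the CP mechanism angle at the pi/4 mode
for kind in ("trihedral", "dihedral"):
    img = g.constant_scene(g.canonical_target(kind))
    cp = g.general_cp_field(img, g.transmit_wave(np.pi / 4, 0))
    _, t2 = g.cp_second_order(cp, window=1)
    print(kind, g.alpha_bcp(t2).values[0, 0])
# trihedral 0.0      <- ideal surface
# dihedral 90.0      <- ideal double bounce

# six-date synthetic rice scene -> feature selection -> SVM
layout = g.default_layout()
schedule = g.default_phenology_schedule()
images, mask = g.build_stack(layout, schedule, seed=7)
stack = g.feature_stack(images, mode="pi4", window=7)
names = g.select_optimal_features(stack, mask, class_a=4, class_b=5, k=8)
pred = g.train_and_classify(stack, names, mask, seed=7)
rep = g.accuracy_report(pred, mask)
print(names[0])                      # alpha_B_1103
print(round(rep.oa, 2), round(rep.kappa, 3))   # 99.94 0.999
```

The top-ranked feature is the harvest-date mechanism angle
(`alpha_B_1103`): on the last date T-H paddies are harvested (bare-soil
surface scattering, low alpha) while D-J is still standing (volume +
double bounce, high alpha), which makes that single date the strongest
discriminator — and the overall accuracy / kappa are computed on
verification parcels disjoint from the training parcels.

The `examples/` directory holds one short narrative script per
capability (canonical scatterers, mode equivalence, speckle filtering,
scene classification, phenology sweep); each prints the numbers it
computes and one line on what they mean. A thin CLI mirrors the library
(`genpol io-validate | cp-simulate | decompose | filter | simulate |
classify | sweep`).

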