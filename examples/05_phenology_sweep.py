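"""Phenological trajectories and the transmit-ellipse sweep.

Tracks the parcel-mean alpha parameter of both rice classes across the
six phenological stages under four transmit modes, then sweeps the
ellipticity angle chi on the harvest date to show how class contrast
depends on the transmit polarization.
"""

import numpy as np

import genpol as g

layout = g.default_layout()
schedule = g.default_phenology_schedule()
images, mask = g.build_stack(layout, schedule, seed=7)

modes = {
    "pi/4 linear": ("general", (np.pi / 4, 0.0)),
    "right circular": ("general", (0.0, -np.pi / 4)),
    "ellipse(45,-20)": ("general", (np.pi / 4, np.radians(-20))),
    "full-pol": ("fp", None),
}
results = {label: [g.decompose_mode(im, m, 7, wave_angles=w)
                   for im in images]
           for label, (m, w) in modes.items()}
curves = g.temporal_curves(results, mask, dates=schedule.dates)

for label in modes:
    for cls in ("T-H", "D-J"):
        sel = curves[(curves["mode"] == label) & (curves["class"] == cls)]
        traj = " ".join(f"{v:5.1f}" for v in sel["alpha_mean"])
        print(f"{label:15s} {cls:4s} alpha: {traj}")
print("stages:", " | ".join(schedule.stages))
print("-> both rice classes rise from seedling to elongation, dip at "
      "booting, plateau, then only T-H drops at harvest.\n")

sweep = g.parameter_sweep(images[5], mask, "chi_at_fixed_theta",
                          np.pi / 4, step=np.radians(15), window=7)
t = sweep.table
rice = t[t["class"].isin(["T-H", "D-J"])]
for chi, grp in rice.groupby("chi"):
    a = {r["class"]: r["alpha_mean"] for _, r in grp.iterrows()}
    print(f"chi = {np.degrees(chi):+5.1f} deg: alpha(T-H) = {a['T-H']:5.1f}, "
          f"alpha(D-J) = {a['D-J']:5.1f}, contrast = "
          f"{abs(a['D-J'] - a['T-H']):4.1f} deg")
print("-> the rice-class contrast in alpha changes continuously with the "
      "transmit ellipticity; for this synthetic harvest scene it peaks "
      "at the circular modes, where the cross-pol of the standing canopy "
      "leaks fully into both receive channels.")
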