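"""Estimate species dive thresholds from pooled depth densities.

Pools centroid depths over the baseline 0.4% cohorts of each species,
fits the kernel density, finds the first local minimum below the mean,
and writes results/thresholds.json plus a density figure.
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from digdive import ChamberGeometry
from digdive.classify import depth_pdf, dive_threshold
from digdive.simulate import preset_params, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_TRIALS = 24

geometry = ChamberGeometry()
out = {}
fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
for ax, condition in zip(axes, ("mel_0.4_noodor", "suzukii_0.4")):
    cohort = simulate_cohort(preset_params(condition), N_TRIALS, seed=SEED, geometry=geometry)
    depths = np.concatenate([traj.z[~traj.missing] for traj, _ in cohort])
    dens = depth_pdf(depths)
    z_div = dive_threshold(dens)
    out[condition] = {
        "z_diving_mm": z_div,
        "z_digging_mm": 0.0,
        "mean_depth_mm": dens.sample_mean,
        "bandwidth_mm": dens.bandwidth,
        "n_frames": len(depths),
    }
    print(
        f"{condition}: mean depth {dens.sample_mean:.2f} mm, "
        f"dive threshold {z_div:.2f} mm (bandwidth {dens.bandwidth:.3f} mm)"
    )
    ax.plot(dens.density, dens.grid, color="crimson")
    ax.axhline(0.0, ls="--", c="k", lw=0.8, label="digging boundary (gel surface)")
    ax.axhline(z_div, ls=":", c="seagreen", label=f"dive threshold {z_div:.2f} mm")
    ax.set_xlabel("density (1/mm)")
    ax.set_title(condition)
    ax.legend(fontsize=7)
axes[0].set_ylabel("centroid depth z (mm)")
fig.tight_layout()
Path("results").mkdir(exist_ok=True)
fig.savefig("results/depth_densities.png", dpi=120)
with open("results/thresholds.json", "w") as fh:
    json.dump(out, fh, indent=2)
print("wrote results/thresholds.json and results/depth_densities.png")
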