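"""Per-trial and cohort dive statistics for the main condition contrasts.

Classifies simulated cohorts at their species thresholds (from
results/thresholds.json if 03 ran, else the preset values), then writes
per-trial summaries, dive-event tables, dive duration/depth ECDFs,
sliding diving-probability series, and the dive-vs-surface-interval
correlation under results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from digdive import BehaviorThresholds, ChamberGeometry, Mode
from digdive.analyze import (
    cohort_aggregates,
    cohort_summary,
    correlate,
    ecdf,
    extract_dives,
    post_dive_intervals,
    sliding_mode_probability,
)
from digdive.classify import classify_modes, flag_inactive
from digdive.io import write_ethogram
from digdive.simulate import preset_params, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_TRIALS = 24
CONDITIONS = ("mel_0.4_noodor", "mel_0.4_odor", "mel_blocked", "suzukii_0.4")

geometry = ChamberGeometry()
results = Path("results")
results.mkdir(exist_ok=True)

thresholds_file = results / "thresholds.json"
species_thr = {}
if thresholds_file.exists():
    est = json.loads(thresholds_file.read_text())
    species_thr["mel"] = est["mel_0.4_noodor"]["z_diving_mm"]
    species_thr["suzukii"] = est["suzukii_0.4"]["z_diving_mm"]
else:
    species_thr["mel"] = preset_params("mel_0.4_noodor").dive_threshold_mm
    species_thr["suzukii"] = preset_params("suzukii_0.4").dive_threshold_mm

agg_rows = []
tracks_by_cond = {}
for condition in CONDITIONS:
    params = preset_params(condition)
    z_div = species_thr["suzukii" if condition.startswith("suzukii") else "mel"]
    thr = BehaviorThresholds(z_diving=z_div)
    cohort = simulate_cohort(params, N_TRIALS, seed=SEED + 100, geometry=geometry)
    mts, trajs, events = [], [], []
    for traj, _ in cohort:
        mt = classify_modes(traj, thr, geometry)
        mt = flag_inactive(traj, mt)
        mts.append(mt)
        trajs.append(traj)
        if mt.inactive_from is None:
            events += extract_dives(mt, traj)
    tracks_by_cond[condition] = mts
    summary = cohort_summary(mts, trajs)
    summary.to_csv(results / f"summary_{condition}.csv", index=False, float_format="%.5g")
    write_ethogram(mts, results / f"ethogram_{condition}.tsv")
    pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "start_s": e.start_s,
                "duration_s": e.duration_s,
                "max_depth_mm": e.max_depth_mm,
                "mean_speed_mm_s": e.mean_speed_mm_s,
            }
            for e in events
        ]
    ).to_csv(results / f"dives_{condition}.csv", index=False, float_format="%.5g")
    agg = cohort_aggregates(summary)
    agg["condition"] = condition
    agg["z_diving_mm"] = z_div
    agg_rows.append(agg)
    print(
        f"{condition}: {agg['dives_per_trial_mean']:.2f} dives/trial, "
        f"{agg['pct_diving_mean']:.1f}% time diving, "
        f"mean dive {agg['dive_duration_mean_s']:.0f} s"
    )

    # duration/depth ECDFs of single dives
    if events:
        for field, name in (("duration_s", "duration"), ("max_depth_mm", "depth")):
            vals = np.array([getattr(e, field) for e in events])
            support, frac = ecdf(vals)
            pd.DataFrame({name: support, "cdf": frac}).to_csv(
                results / f"ecdf_{name}_{condition}.tsv", sep="\t", index=False, float_format="%.5g"
            )

pd.DataFrame(agg_rows).to_csv(results / "cohort_aggregates.csv", index=False, float_format="%.4g")

# sliding diving probability, odor vs no odor
for condition in ("mel_0.4_noodor", "mel_0.4_odor"):
    series = sliding_mode_probability(tracks_by_cond[condition], Mode.DIVING, window_s=60.0)
    pd.DataFrame(
        {"time_s": series.times, "p_diving": series.probability, "n_trials": series.n_trials}
    ).to_csv(results / f"p_diving_{condition}.csv", index=False, float_format="%.5g")

# dive duration vs subsequent surface interval (pooled over the baseline cohort)
pairs = []
for mt in tracks_by_cond["mel_0.4_noodor"]:
    pairs += post_dive_intervals(mt)
if len(pairs) >= 3:
    rho, p = correlate(pairs)
    with open(results / "dive_surface_correlation.json", "w") as fh:
        json.dump({"n_pairs": len(pairs), "spearman_rho": rho, "p_value": p}, fh, indent=2)
    print(f"dive vs surface interval: rho = {rho:.3f}, p = {p:.3f} ({len(pairs)} pairs)")
print("wrote per-condition tables under results/")
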