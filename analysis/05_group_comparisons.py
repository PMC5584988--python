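"""Statistical comparisons between condition cohorts.

Reads the per-trial summaries written by 04 (re-deriving them if
absent), then runs the normality-gated pairwise tests, the multi-group
Kruskal-Wallis with compact letters across gel-hardness presets, and
the power/sample-size calculations.  Writes results/group_stats.json.
"""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from digdive.stats import (
    PowerSpec,
    cohens_d,
    kruskal_posthoc,
    rank_sum_test,
    sample_size_t,
    select_test,
    t_power,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
results = Path("results")
if not (results / "summary_mel_0.4_noodor.csv").exists():
    subprocess.run([sys.executable, "analysis/04_dive_statistics.py", str(SEED)], check=True)


def pct_diving(condition):
    return pd.read_csv(results / f"summary_{condition}.csv")["pct_diving"].to_numpy()


report = {}

# respiration contrast: intact vs blocked posterior spiracles
intact, blocked = pct_diving("mel_0.4_noodor"), pct_diving("mel_blocked")
res = select_test(intact, blocked, n_mc=2000, seed=SEED)
report["diving_intact_vs_blocked"] = {
    "test": res.test_name,
    "statistic": res.statistic,
    "p_value": res.p_value,
    "n": res.n,
}
print(f"intact vs blocked spiracles ({res.test_name}): p = {res.p_value:.2e}")

# species contrast at matched gel hardness
mel, suz = pct_diving("mel_0.4_noodor"), pct_diving("suzukii_0.4")
res = rank_sum_test(mel, suz)
report["diving_mel_vs_suzukii"] = {
    "test": res.test_name,
    "statistic": res.statistic,
    "p_value": res.p_value,
    "cohens_d": cohens_d(mel, suz),
}
print(f"melanogaster vs suzukii (rank-sum): p = {res.p_value:.2e}")

# odor effect
noodor, odor = pct_diving("mel_0.4_noodor"), pct_diving("mel_0.4_odor")
res = rank_sum_test(noodor, odor)
report["diving_noodor_vs_odor"] = {
    "test": res.test_name,
    "statistic": res.statistic,
    "p_value": res.p_value,
}
print(f"no odor vs odor (rank-sum): p = {res.p_value:.3f}")

# gel hardness: multi-group comparison with compact letters
from digdive import BehaviorThresholds, ChamberGeometry
from digdive.analyze import mode_time_fractions
from digdive.classify import classify_modes, flag_inactive
from digdive.core import Mode
from digdive.simulate import preset_params, simulate_cohort

geometry = ChamberGeometry()
hardness = ("mel_soft_0.05", "mel_0.4_noodor", "mel_hard_2.0")
groups = []
for condition in hardness:
    params = preset_params(condition)
    thr = BehaviorThresholds(z_diving=params.dive_threshold_mm)
    vals = []
    for traj, _ in simulate_cohort(params, 24, seed=SEED + 200, geometry=geometry):
        mt = flag_inactive(traj, classify_modes(traj, thr, geometry))
        if mt.inactive_from is None:
            vals.append(mode_time_fractions(mt)[Mode.DIVING])
    groups.append(np.array(vals))
kp = kruskal_posthoc(groups)
report["diving_by_hardness"] = {
    "conditions": list(hardness),
    "kruskal_p": kp.kruskal_p,
    "pairwise_p": kp.pairwise_p.tolist(),
    "letters": list(kp.letters),
}
print("diving % across gel hardness:", dict(zip(hardness, kp.letters)), f"(KW p = {kp.kruskal_p:.2e})")

# power designs used to size the assays
designs = {
    "small_effect": PowerSpec(mu=0.15, sigma=0.1, delta=0.05),
    "large_effect": PowerSpec(mu=0.5, sigma=0.2, delta=0.3),
}
report["sample_sizes"] = {}
for name, spec in designs.items():
    n0 = sample_size_t(spec)
    report["sample_sizes"][name] = {
        "n0": n0,
        "power_at_n0": t_power(n0, spec),
        "effect_size_d": spec.effect_size,
    }
    print(f"{name}: n0 = {n0} (power {t_power(n0, spec):.3f} at d = {spec.effect_size:.2f})")

with open(results / "group_stats.json", "w") as fh:
    json.dump(report, fh, indent=2)
print("wrote results/group_stats.json")
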