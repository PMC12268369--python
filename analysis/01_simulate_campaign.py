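#!/usr/bin/env python
"""Generate the synthetic LC-FTMS campaign and characterize its structure.

Emulates the study conditions: 95 seawater samples, ten 1-min retention-time
segments, CHNOS formulas (DBE-O <= 10, 150-1000 Da), a ~79.3% zero-filled
time-aware table, and a C475 fluorescence proxy linear in the latent
terrestrial fraction.  Writes the long table to scratch/ (it is bulky and
fully reproducible from the seed) and a compact summary to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from terradom.io import write_long_table
from terradom.simulate import GeneratorConfig, generate_dataset
from terradom.tables import build_time_agnostic, build_time_aware

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

cfg = GeneratorConfig(seed=args.seed)
ds = generate_dataset(cfg)
aware = build_time_aware(ds.long)
agnostic = build_time_agnostic(ds.long)

summary = pd.Series({
    "n_samples": cfg.n_samples,
    "n_formulas": cfg.n_formulas,
    "n_segments": cfg.n_segments,
    "n_records": len(ds.long.records),
    "time_aware_features": aware.n_features,
    "time_agnostic_features": agnostic.n_features,
    "time_aware_zero_fraction": round(aware.zero_fraction(), 4),
    "ubiquitous_mfrt": int(aware.ubiquitous_mask().sum()),
    "ubiquitous_mf": int(agnostic.ubiquitous_mask().sum()),
    "c475_min": round(ds.long.c475.min(), 5),
    "c475_max": round(ds.long.c475.max(), 5),
    "terrestrial_mean_mass_da": round(ds.profile.weighted_mean_mass("terrestrial"), 1),
    "marine_mean_mass_da": round(ds.profile.weighted_mean_mass("marine"), 1),
    "terrestrial_n_to_c": round(ds.profile.weighted_ratio("terrestrial", "N"), 4),
    "marine_n_to_c": round(ds.profile.weighted_ratio("marine", "N"), 4),
})

Path("scratch").mkdir(exist_ok=True)
Path("results").mkdir(exist_ok=True)
write_long_table(ds.long, "scratch/long_table.tsv", header_meta={"seed": args.seed})
summary.rename("value").to_csv("results/01_campaign_summary.tsv", sep="\t",
                               index_label="quantity")

print("synthetic campaign characteristics")
print(summary.to_string())
print("\nThe time-aware table reproduces the campaign's sparsity; the "
      "terrestrial end member sits at lower mass and lower N/C than the "
      "marine one, as intended.")
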