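#!/usr/bin/env python
"""Recursive feature elimination: how many features does the forest need?

Runs OOB-permutation-importance-driven RFE (10% steps, cross-validated
error from the omitted folds) on the ubiquitous sum-normalized time-aware
table of the seeded campaign.
"""

import argparse
from pathlib import Path

from terradom.importance import recursive_feature_elimination
from terradom.preprocess import PreprocessSpec, preprocess_table
from terradom.simulate import GeneratorConfig, generate_dataset
from terradom.tables import build_time_aware

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-trees", type=int, default=30)
args = ap.parse_args()

ds = generate_dataset(GeneratorConfig(seed=args.seed))
table = preprocess_table(build_time_aware(ds.long),
                         PreprocessSpec("time_aware", "ubiquitous", "SUM"),
                         doc=ds.long.doc)

curve = recursive_feature_elimination(
    table.values, ds.long.c475.to_numpy(),
    {"n_trees": args.n_trees, "mtry": max(1, table.n_features // 3),
     "min_node_size": 5},
    step_fraction=0.1, k=5, seed=args.seed,
)

Path("results").mkdir(exist_ok=True)
curve.to_csv("results/03_rfe_curve.tsv", sep="\t", index=False)

best = curve.loc[curve["cv_nrmse_pct"].idxmin()]
print(curve.to_string(index=False))
print(f"\nstarting from {curve['n_features'].iloc[0]} features, the minimum "
      f"CV NRMSE of {best['cv_nrmse_pct']:.2f}% is reached at "
      f"{int(best['n_features'])} features.")
print("Because a single latent mixing fraction drives every synthetic "
      "feature, the curve stays flat down to very few features; field data "
      "with many independent chemical drivers degrade earlier.")
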