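#!/usr/bin/env python
"""Benchmark the four model families over preprocessing combinations.

Regenerates the seeded campaign of 01 and fits elastic-net GLM, random
forest, and polynomial/RBF SVR on a representative slice of the 32
preprocessing combinations (both table layouts, with and without the
ubiquitous filter, SUM/UBISUM/DOC-N/ALR normalizations).  Hyperparameter
grids are reduced ladders of the full search so the run stays at desk
scale; the full grids remain available through the library defaults.
"""

import argparse
from pathlib import Path

from terradom import models as mod
from terradom.preprocess import PreprocessSpec
from terradom.simulate import GeneratorConfig, generate_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

ds = generate_dataset(GeneratorConfig(seed=args.seed))
long = ds.long

specs = [
    PreprocessSpec(fmt, elim, norm)
    for fmt in ("time_aware", "time_agnostic")
    for elim in ("ubiquitous", "no_low_variance")
    for norm in ("SUM", "UBISUM", "DOC-N", "ALR")
]

glm_grid = mod.ModelGrid(
    "GLM_elastic_net",
    tuple({"alpha": a, "lam": l}
          for a in (0.0, 0.5, 1.0) for l in (0.0, 0.05, 0.25, 1.0)),
)
rf_grid = mod.ModelGrid(
    "RF", tuple({"n_trees": 60, "mtry": m, "min_node_size": s}
                for m in (5, 20) for s in (3, 7)),
)
poly_grid = mod.ModelGrid(
    "SVR_poly", tuple({"cost": c, "degree": d, "scale": 1.0}
                      for c in (0.25, 1.0) for d in (1, 2)),
)
rbf_grid = mod.ModelGrid(
    "SVR_rbf", tuple({"cost": c, "sigma": s}
                     for c in (0.25, 1.0) for s in (1e-4, 1e-2, 1.0)),
)

results, fits = mod.run_benchmark(
    long, specs, families=mod.FAMILIES, seed=args.seed,
    grids={"GLM_elastic_net": glm_grid, "RF": rf_grid,
           "SVR_poly": poly_grid, "SVR_rbf": rbf_grid},
    k=5, repeats=2,
)

Path("results").mkdir(exist_ok=True)
results.to_csv("results/02_benchmark_cells.tsv", sep="\t", index=False)
heat = mod.heatmap_table(results)
heat.round(2).to_csv("results/02_benchmark_heatmap.tsv", sep="\t")

ok = results[results["error"] == ""]
best = ok.loc[ok["nrmse_pct"].idxmin()]
print(f"{len(ok)}/{len(results)} cells fitted")
print("\nNRMSE (% of the C475 range) heatmap:")
print(heat.round(2).to_string())
print(f"\nbest cell: {best['spec']} with {best['family']} "
      f"-> NRMSE {best['nrmse_pct']:.2f}% (R^2 {best['r2']:.3f})")
print("On this synthetic campaign the time-aware tables predict best and "
      "SUM equals UBISUM exactly on the ubiquitous branch.  Averaging over "
      "detected segments (time-agnostic layout) distorts the linear "
      "feature-target relationship, which hurts the GLM and SVR cells but "
      "barely affects the random forest.")
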