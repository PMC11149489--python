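#!/usr/bin/env python
"""Spatial clustering of STAT3 activation in synthetic tissue fields.

Generates a clustered field (discs of elevated nuclear/cytoplasmic ratio)
and an iid control, computes the k-nearest-neighbour correlation profile
(Spearman, with the Pearson variant alongside) over the neighbourhood
ladder, and contrasts both against seeded permutation null bands.

Writes results/spatial/{profile_clustered.csv, profile_iid.csv}.
"""

from pathlib import Path

from fluxsort import spatial, synthetic_data as sd
from fluxsort.synthetic_data import GeneratorConfig

OUT = Path("results/spatial")
OUT.mkdir(parents=True, exist_ok=True)

KS = (3, 10, 100, 1000)

for label, scale in (("clustered", 60.0), ("iid", 0.0)):
    df, truth = sd.gen_spatial_field(
        GeneratorConfig(seed=600, n_cells=4000), cluster_scale=scale, effect=2.5
    )
    table = spatial.SpatialCellTable.from_frame(df)
    prof = spatial.correlation_profile(table, ks=KS, method="spearman")
    band = spatial.permutation_band(table, ks=KS, method="spearman",
                                    n_perm=200, seed=601)
    merged = prof.merge(band, on=["k", "method"], how="left")
    merged.to_csv(OUT / f"profile_{label}.csv", index=False)
    print(f"{label} field (cluster scale {scale:g} um):")
    print(merged[["k", "correlation", "permutation_lo", "permutation_hi"]]
          .round(3).to_string(index=False))
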