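"""Screen the flagged ASRRs against a library of region-set profiles.

Two complementary statistics per library entry: Pearson correlation of
covered bp in 50 kb genome-tiling windows, and a permutation test that
re-places the query regions uniformly at random (lengths preserved)
and counts query regions overlapping the target. The planted
K9me2_L3_like profile co-locates with the ASRRs and should rank first;
the random decoys should not.
"""

from chromage.association import rank_associations
from chromage.differential import classify_asrr, differential_enrichment
from chromage.genome import RegionSet
from chromage.pipeline import load_fixture, pooled_zscore_ratio, region_mean_track

from _common import ensure_fixture

fx = load_fixture(ensure_fixture())

res = differential_enrichment(fx.chip)
young_z = region_mean_track(pooled_zscore_ratio(fx.tracks, ages=("young",)),
                            fx.chip.features.loc[res.table.index])
res = classify_asrr(res, young_z)
asrr_ids = res.table.index[res.table["asrr"]]
query = RegionSet(fx.chip.features.loc[asrr_ids].reset_index().rename(
    columns={"feature_id": "name"})[["chrom", "start", "end", "name"]], label="asrr")
print(f"query: {len(query)} flagged ASRRs; library: {len(fx.library)} profiles")

table = rank_associations(query, fx.library, fx.layout, window=50_000,
                          n_perm=2000, seed=7)
cols = ["target", "pearson_r", "obs", "null_mean", "perm_z", "perm_p", "best_rank"]
print(table[cols].round(3).to_string(index=False))
print("\ntop-ranked profile:", table.iloc[0]["target"])
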