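"""Double-contrast differential enrichment and ASRR classification.

For each region the statistic is the change with age of the
H3-normalised mark signal: (old mark - old control) - (young mark -
young control) on the log2 scale, tested with a moderated t whose
per-region variances are shrunk toward a pooled prior. A region is an
aging-specific repressive region (ASRR) when it gains mark with age
(direction 'up', BH q < 0.05) AND its young-age z-scored signal is
below zero, i.e. it was not repressive to begin with.
"""

import pandas as pd

from chromage.differential import classify_asrr, differential_enrichment, mds_embed, normalized_log_counts
from chromage.pipeline import load_fixture, pooled_zscore_ratio, region_mean_track

from _common import ensure_fixture

fx = load_fixture(ensure_fixture())

res = differential_enrichment(fx.chip, alpha=0.05)
print("features tested :", len(res.table))
print("up with age     :", int((res.table['direction'] == 'up').sum()))
print("down with age   :", int((res.table['direction'] == 'down').sum()))
print(f"variance prior  : d0={res.d0}, s0^2={res.s0_sq:.4g}")

young_z = region_mean_track(pooled_zscore_ratio(fx.tracks, ages=("young",)),
                            fx.chip.features.loc[res.table.index])
res = classify_asrr(res, young_z, asrr_z_max=0.0)
flagged = res.table[res.table["asrr"]]
print("ASRRs flagged   :", len(flagged))

planted = set(fx.truth.asrrs["id"])
tp = len(planted & set(flagged.index))
print(f"vs truth        : sensitivity {tp / len(planted):.2f}, "
      f"false discoveries {len(set(flagged.index) - planted)}")

print("\ntop flagged regions:")
print(flagged.sort_values("q")[["delta", "q", "young_mean_z"]].head().to_string())

# MDS overview: replicates should pair, ages should separate
logc = normalized_log_counts(fx.chip)
mark_cols = [r["column"] for _, r in logc.attrs["pairs"].iterrows()]
emb = mds_embed(logc[mark_cols])
print("\nMDS of mark/control log ratios (dim1 separates ages):")
print(emb.coords.round(3).to_string())
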