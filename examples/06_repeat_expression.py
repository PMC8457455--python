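"""Locus-level repeat expression: counting policies, fractions, DE,
family enrichment and the mark fold-change join.

Repeat-derived RNA reads often match several copies of a family. The
'all' policy credits every matched locus (one count each); 'unique'
keeps only single-locus reads. Repeat transcriptome fractions are
computed on distinct reads against whole-transcriptome totals, so they
stay in [0, 1] and capture the genuine rise of repeat output with age.
"""

import pandas as pd

from chromage.repeats import (count_repeat_reads, differential_repeats,
                              group_enrichment, repeat_fraction, unmapped_fraction)

from _common import ensure_fixture
from chromage.pipeline import load_fixture

fx = load_fixture(ensure_fixture())
meta = fx.rna_samples[["age", "assay", "replicate"]]
total_mapped = fx.rna_samples["total_mapped"].astype(float)

cm_all = count_repeat_reads(fx.placements, fx.annotation, meta, policy="all",
                            total_mapped=total_mapped)
cm_uni = count_repeat_reads(fx.placements, fx.annotation, meta, policy="unique",
                            total_mapped=total_mapped)
print("total locus counts, 'all' policy   :", int(cm_all.counts.to_numpy().sum()))
print("total locus counts, 'unique' policy:", int(cm_uni.counts.to_numpy().sum()))

frac, t, p = repeat_fraction(fx.placements, total_mapped, meta["age"])
print("\nrepeat fraction of the transcriptome per sample:")
print(frac.round(4).to_string())
print(f"old vs young t-test: t={t:.2f}, p={p:.3g}")
print("unmapped fraction:", unmapped_fraction(fx.placements).round(4).to_dict())

diff = differential_repeats(cm_all, alpha=0.01, min_count=5)
n_up = int((diff.table["direction"] == "up").sum())
n_down = int((diff.table["direction"] == "down").sum())
print(f"\nexpressed loci tested: {len(diff.table)}; up {n_up}, down {n_down}")

enr = group_enrichment(diff, fx.annotation, level="family", side="up")
print("\nfamily over-representation among up loci:")
print(enr[["group", "k", "K", "n", "N", "q"]].to_string(index=False))
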