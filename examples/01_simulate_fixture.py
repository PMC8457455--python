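"""Generate the synthetic aging-chromatin dataset and look inside it.

The generator plants a small three-chromosome genome with repeat-rich
arms, 30 constitutive repressive domains, 20 aging-specific repressive
regions (ASRRs: background mark level when young, 2.5-fold enriched when
old), 150 stable background regions, fragmented peak calls, per-sample
coverage tracks, and a multi-copy repeat family with a planted 4-fold
old-age expression increase. truth.json records everything planted.
"""

from chromage.pipeline import load_fixture

from _common import ensure_fixture

fixture_dir = ensure_fixture(seed=1)
fx = load_fixture(fixture_dir)

print("chromosomes:", {c: fx.layout.length(c) for c in fx.layout.chrom_names})
print("fragmented peak calls:", len(fx.peaks))
print("ChIP count matrix:", fx.chip.counts.shape, "features x samples")
print("samples:", ", ".join(fx.chip.samples.index))
print("coverage tracks:", len(fx.tracks), "(mark, control, active) x age x replicate")
print("repeat loci annotated:", len(fx.annotation.table))
print("RNA read placements:", len(fx.placements))
print("association library:", ", ".join(sorted(fx.library)))

truth = fx.truth
print("\nplanted truth:")
print("  domains:", len(truth.domains), "ASRRs:", len(truth.asrrs),
      "background:", len(truth.background))
print("  ASRR old/young enrichment:",
      truth.asrrs["old_enrichment"].iloc[0], "/",
      truth.asrrs["young_enrichment"].iloc[0])
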