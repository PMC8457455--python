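"""Run both end-to-end workflows and print the report highlights.

Equivalent to `chromage run-chip` + `chromage run-repeats` on the same
output directory (sharing the directory lets the repeat workflow join
its fold changes against the ChIP differential table).
"""

from pathlib import Path

from chromage.pipeline import PipelineConfig, run_chip_workflow, run_repeat_workflow

from _common import ensure_fixture

out = Path(__file__).resolve().parent / "example_out"
cfg = PipelineConfig(fixture_dir=str(ensure_fixture()), out_dir=str(out))

chip = run_chip_workflow(cfg)
rep = run_repeat_workflow(cfg)

print("ChIP workflow:")
print(f"  peaks -> domains          : {chip['n_input_peaks']} -> {chip['n_merged_domains']}")
print(f"  differential (q<0.05)     : {chip['n_up']} up, {chip['n_down']} down")
print(f"  ASRRs flagged             : {chip['n_asrr']}")
conf = chip["asrr_confusion"]
print(f"  vs truth                  : sensitivity {conf['sensitivity']:.2f}, FDR {conf['fdr']:.2f}")
print(f"  metaplot body / flank z   : {chip['metaplot_body_mean_z']:.3f} / {chip['metaplot_flank_mean_z']:.3f}")
bc = chip["boundary_contrast_mean"]
print(f"  boundary contrast y / o   : {bc['young']:.3f} / {bc['old']:.3f}")
print(f"  association top target    : {chip['association_top_target']}")

print("\nRepeat workflow:")
frac = rep["repeat_fraction"]
young = [v for k, v in frac.items() if "young" in k]
old = [v for k, v in frac.items() if "old" in k]
print(f"  repeat fraction young/old : {sum(young)/len(young):.4f} / {sum(old)/len(old):.4f}")
print(f"  expressed loci            : {rep['n_expressed']}")
print(f"  differential (q<0.01)     : {rep['n_up']} up, {rep['n_down']} down")
top = rep["enrichment"]["family_up_top"]
print(f"  top family (up)           : {top['group']} (q={top['q']:.3g})")
r = rep["rna_mark_fc_correlation"]
print(f"  RNA vs mark fold-change r : {r['pearson_r']:.3f} (n={int(r['n_paired'])})")
print(f"\nall tables and reports in {out}")
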