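"""End-to-end workflows wiring the analysis stages together.

Two workflows mirror the study design: the ChIP aging analysis (peak
union -> domain merging -> double-contrast differential -> ASRR
classification -> compartment summary -> metaplots/boundary contrasts ->
MDS -> region-set association screen) and the repeat expression analysis
(multi-mapper counting -> transcriptome fractions -> differential ->
family/class enrichment -> mark fold-change join). Both are
deterministic under a fixed configuration and write a run manifest
echoing every parameter and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import (DataError, GenomeLayout, RegionSet, read_bed, write_bed,
                     partition_by_compartment, union_regions)
from .tracks import (BinnedTrack, boundary_contrast, compute_matrix, log2_ratio_track,
                     read_bedgraph, summarize_matrix, zscore_track)
from .domains import MergeConfig, gap_threshold_scan, merge_adjacent_peaks
from .differential import (CountMatrix, classify_asrr, differential_enrichment,
                           fold_change_groups, mds_embed, normalized_log_counts)
from .association import rank_associations
from .repeats import (RepeatAnnotation, count_repeat_reads, differential_repeats,
                      expressed_silent_partition, group_enrichment, locus_mark_fc_table,
                      read_placements, repeat_fraction, unmapped_fraction)
from .simulate import TruthManifest

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Unknown keys are rejected when loading from a dict or file so typos
    cannot silently fall back to defaults.
    """

    fixture_dir: str = ""
    out_dir: str = "chromage_out"
    max_gap: int = 5000
    smooth: int = 60
    alpha: float = 0.05
    asrr_z_max: float = 0.0
    flank: int = 2000
    body_bins: int = 100
    boundary_w: int = 1000
    assoc_window: int = 50_000
    n_perm: int = 2000
    seed: int = 7
    policy: str = "all"
    alpha_rna: float = 0.01
    min_count: int = 5
    r_threshold: float = 0.45
    z_threshold: float = 34.0
    gap_scan_thresholds: tuple[int, ...] = (0, 1000, 2000, 3000, 4000, 5000, 8000)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "gap_scan_thresholds" in kwargs and isinstance(kwargs["gap_scan_thresholds"], str):
            kwargs["gap_scan_thresholds"] = tuple(
                int(x) for x in kwargs["gap_scan_thresholds"].split(","))
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value configuration file (comments with #)."""
        d: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataError(f"{path}:{lineno}: expected key=value")
            key, val = (x.strip() for x in line.split("=", 1))
            d[key] = val
        cfg = cls.from_dict({})
        typed: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            raw = d.pop(f.name)
            if f.name == "gap_scan_thresholds":
                typed[f.name] = raw
            elif isinstance(getattr(cfg, f.name), bool):
                typed[f.name] = str(raw).lower() in ("1", "true", "yes")
            elif isinstance(getattr(cfg, f.name), int):
                typed[f.name] = int(raw)
            elif isinstance(getattr(cfg, f.name), float):
                typed[f.name] = float(raw)
            else:
                typed[f.name] = raw
        if d:
            raise DataError(f"unknown config keys: {sorted(d)}")
        return cls.from_dict(typed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gap_scan_thresholds"] = list(self.gap_scan_thresholds)
        return d


# ---- fixture loading -----------------------------------------------------


@dataclass
class FixtureData:
    layout: GenomeLayout
    peaks: RegionSet
    chip: CountMatrix
    tracks: dict[tuple[str, str, int], BinnedTrack]
    annotation: RepeatAnnotation | None
    placements: pd.DataFrame | None
    rna_samples: pd.DataFrame | None
    library: dict[str, RegionSet]
    truth: TruthManifest | None
    track_bin: int


def load_fixture(directory: str | Path) -> FixtureData:
    directory = Path(directory)
    if not directory.exists():
        raise DataError(f"fixture directory {directory} does not exist")
    layout = GenomeLayout.from_files(directory / "chrom.sizes", directory / "compartments.bed")
    peaks = read_bed(directory / "peaks.bed")
    counts_df = pd.read_csv(directory / "chip_counts.tsv", sep="\t", index_col=0)
    features = counts_df[["chrom", "start", "end"]]
    samples = pd.read_csv(directory / "chip_samples.tsv", sep="\t", index_col=0)
    lib = samples["library_size"].astype(float)
    chip = CountMatrix(counts_df.drop(columns=["chrom", "start", "end"]).astype(np.int64),
                       samples[["age", "assay", "replicate"]], features, lib)
    track_bin = 200
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        track_bin = int(json.loads(cfg_path.read_text()).get("track_bin", track_bin))
    tracks = {}
    for path in sorted((directory / "tracks").glob("*.bedgraph")):
        assay, age, rep = path.stem.rsplit("_", 2)
        tracks[(assay, age, int(rep.replace("rep", "")))] = read_bedgraph(
            path, layout, track_bin, kind="coverage")
    annotation = placements = rna_samples = None
    if (directory / "repeat_annotation.tsv").exists():
        annotation = RepeatAnnotation.from_tsv(directory / "repeat_annotation.tsv")
        placements = read_placements(directory / "repeat_placements.tsv")
        rna_samples = pd.read_csv(directory / "rna_samples.tsv", sep="\t", index_col=0)
    library = {}
    lib_dir = directory / "assoc_library"
    if lib_dir.exists():
        for path in sorted(lib_dir.glob("*.bed")):
            rs = read_bed(path)
            rs.label = path.stem
            library[path.stem] = rs
    truth = None
    if (directory / "truth.json").exists():
        truth = TruthManifest.from_json(directory / "truth.json")
    return FixtureData(layout, peaks, chip, tracks, annotation, placements,
                       rna_samples, library, truth, track_bin)


def _pooled(tracks: dict, assay: str, ages=("young", "old")) -> BinnedTrack:
    """Sum coverage over replicates (and ages) for one assay."""
    picked = [t for (a, age, _r), t in tracks.items() if a == assay and age in ages]
    if not picked:
        raise DataError(f"no {assay} tracks for ages {ages}")
    base = picked[0]
    values = {c: sum(t.values[c] for t in picked) for c in base.values}
    return BinnedTrack(base.layout, base.bin_size, values, None, kind="coverage")


def pooled_zscore_ratio(tracks: dict, ages=("young", "old"), assay: str = "mark",
                        smooth: int = 60) -> BinnedTrack:
    ratio = log2_ratio_track(_pooled(tracks, assay, ages), _pooled(tracks, "control", ages),
                             smooth=smooth)
    return zscore_track(ratio)


def region_mean_track(track: BinnedTrack, features: pd.DataFrame) -> pd.Series:
    vals = {fid: track.region_mean(row["chrom"], int(row["start"]), int(row["end"]))
            for fid, row in features.iterrows()}
    return pd.Series(vals)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_chip_workflow(config: PipelineConfig) -> dict:
    """ChIP aging analysis end to end; returns the report dict."""
    fx = load_fixture(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"workflow": "chip", "version": __version__,
                    "parameters": config.to_dict(), "seed": config.seed, "warnings": {}}

    # 1. union + domain reconstruction on the pooled two-age ratio track
    union = union_regions([fx.peaks], fx.layout)
    merge_track = pooled_zscore_ratio(fx.tracks, smooth=config.smooth)
    merged = merge_adjacent_peaks(union, merge_track, MergeConfig(config.max_gap))
    write_bed(merged, out / "merged_domains.bed")
    scan = gap_threshold_scan(union, merge_track, list(config.gap_scan_thresholds))
    _write_tsv(scan, out / "gap_threshold_scan.tsv", index=False)
    report["n_input_peaks"] = len(union)
    report["n_merged_domains"] = len(merged)

    # 2. differential enrichment + ASRR classification
    res = differential_enrichment(fx.chip, alpha=config.alpha)
    young_track = pooled_zscore_ratio(fx.tracks, ages=("young",), smooth=config.smooth)
    young_z = region_mean_track(young_track, fx.chip.features.loc[res.table.index])
    res = classify_asrr(res, young_z, asrr_z_max=config.asrr_z_max)
    res.table["fold_group"] = fold_change_groups(res.table["delta"].to_numpy())
    diff_out = fx.chip.features.loc[res.table.index, ["chrom", "start", "end"]].join(res.table)
    _write_tsv(diff_out, out / "differential.tsv")
    report["n_features_tested"] = len(res.table)
    report["n_excluded_zero"] = len(res.excluded)
    report["n_up"] = int((res.table["direction"] == "up").sum())
    report["n_down"] = int((res.table["direction"] == "down").sum())
    report["n_asrr"] = int(res.table["asrr"].sum())
    report["moderation"] = {"d0": res.d0 if np.isfinite(res.d0) else "inf", "s0_sq": res.s0_sq}

    # 3. compartment summary of tested regions by direction
    feat_rs = RegionSet(fx.chip.features.loc[res.table.index].reset_index().rename(
        columns={"feature_id": "name"})[["chrom", "start", "end", "name"]])
    comp = pd.Series(partition_by_compartment(feat_rs, fx.layout), index=feat_rs.df["name"])
    summary = pd.crosstab(comp.reindex(res.table.index), res.table["direction"])
    summary.index.name = "compartment"
    _write_tsv(summary, out / "compartment_summary.tsv")
    report["compartment_summary"] = {str(k): {str(c): int(v) for c, v in row.items()}
                                     for k, row in summary.iterrows()}

    # 4. metaplot over merged domains + boundary contrasts per age
    meta, n_short = compute_matrix(merge_track, merged, flank=config.flank,
                                   body_bins=config.body_bins)
    _write_tsv(summarize_matrix(meta), out / "metaplot_summary.tsv", index=False)
    report["warnings"]["metaplot_short_regions"] = n_short
    body = meta.values[:, meta.flank_bins:meta.flank_bins + meta.body_bins]
    flankv = np.concatenate([meta.values[:, :meta.flank_bins],
                             meta.values[:, meta.flank_bins + meta.body_bins:]], axis=1)
    report["metaplot_body_mean_z"] = float(body[meta.mask[:, meta.flank_bins:meta.flank_bins + meta.body_bins]].mean())
    report["metaplot_flank_mean_z"] = float(flankv[np.concatenate(
        [meta.mask[:, :meta.flank_bins], meta.mask[:, meta.flank_bins + meta.body_bins:]], axis=1)].mean())

    boundary_rows = []
    skipped = 0
    for age in ("young", "old"):
        active_z = zscore_track(log2_ratio_track(_pooled(fx.tracks, "active", (age,)),
                                                 _pooled(fx.tracks, "control", (age,)),
                                                 smooth=config.smooth))
        table, n_skip = boundary_contrast(active_z, merged, w=config.boundary_w, mark="active")
        table.insert(0, "age", age)
        boundary_rows.append(table)
        skipped += n_skip
    boundary = pd.concat(boundary_rows, ignore_index=True)
    _write_tsv(boundary, out / "boundary_contrast.tsv", index=False)
    report["warnings"]["boundary_edges_skipped"] = skipped
    bmeans = boundary.groupby("age")["contrast"].mean()
    report["boundary_contrast_mean"] = {a: float(v) for a, v in bmeans.items()}

    # 5. MDS overview of samples
    logc = normalized_log_counts(fx.chip)
    mark_cols = [r["column"] for _, r in logc.attrs["pairs"].iterrows()]
    emb = mds_embed(logc[mark_cols])
    _write_tsv(emb.coords.join(fx.chip.samples[["age", "assay"]]), out / "mds.tsv")
    report["mds_degenerate"] = emb.degenerate

    # 6. association screen of ASRRs against the library
    asrr_ids = res.table.index[res.table["asrr"]]
    if len(asrr_ids) and fx.library:
        query = RegionSet(fx.chip.features.loc[asrr_ids].reset_index().rename(
            columns={"feature_id": "name"})[["chrom", "start", "end", "name"]], label="asrr")
        assoc = rank_associations(query, fx.library, fx.layout, window=config.assoc_window,
                                  n_perm=config.n_perm, seed=config.seed,
                                  r_threshold=config.r_threshold, z_threshold=config.z_threshold)
        _write_tsv(assoc, out / "association.tsv", index=False)
        report["association_top_target"] = str(assoc.iloc[0]["target"])
    else:
        report["association_top_target"] = None

    # 7. confusion against the truth manifest, when present
    if fx.truth is not None and len(fx.truth.asrrs):
        planted = set(fx.truth.asrrs["id"])
        flagged = set(asrr_ids)
        tp = len(planted & flagged)
        fp = len(flagged - planted)
        fn = len(planted - flagged)
        report["asrr_confusion"] = {
            "planted": len(planted), "flagged": len(flagged),
            "tp": tp, "fp": fp, "fn": fn,
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "fdr": fp / len(flagged) if flagged else 0.0,
        }
        report["domain_recovery"] = {
            "planted_regions": int(len(fx.truth.domains) + len(fx.truth.asrrs)),
            "merged_regions": len(merged),
        }

    (out / "chip_report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                     default=_json_default))
    return report


def run_repeat_workflow(config: PipelineConfig) -> dict:
    """Repeat expression analysis end to end; returns the report dict."""
    fx = load_fixture(config.fixture_dir)
    if fx.annotation is None or fx.placements is None or fx.rna_samples is None:
        raise DataError("fixture lacks repeat annotation/placements")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"workflow": "repeats", "version": __version__,
                    "parameters": config.to_dict(), "seed": config.seed, "warnings": {}}
    meta = fx.rna_samples[["age", "assay", "replicate"]]
    total_mapped = fx.rna_samples["total_mapped"].astype(float)

    cm_all = count_repeat_reads(fx.placements, fx.annotation, meta, policy="all",
                                total_mapped=total_mapped)
    cm_unique = count_repeat_reads(fx.placements, fx.annotation, meta, policy="unique",
                                   total_mapped=total_mapped)
    _write_tsv(cm_all.counts, out / "repeat_counts_all.tsv")
    _write_tsv(cm_unique.counts, out / "repeat_counts_unique.tsv")
    report["policy_dominance_ok"] = bool((cm_unique.counts.to_numpy() <= cm_all.counts.to_numpy()).all())

    if len(fx.placements) == 0:
        report["repeat_fraction"] = {}
        report["n_differential"] = 0
        (out / "repeat_report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                           default=_json_default))
        return report

    frac, t, p = repeat_fraction(fx.placements, total_mapped, meta["age"])
    unmapped = unmapped_fraction(fx.placements)
    _write_tsv(pd.DataFrame({"repeat_fraction": frac, "unmapped_fraction": unmapped}),
               out / "repeat_fractions.tsv")
    report["repeat_fraction"] = {k: float(v) for k, v in frac.items()}
    report["repeat_fraction_ttest"] = {"t": t, "p": p}
    report["unmapped_fraction"] = {k: float(v) for k, v in unmapped.items()}

    cm = cm_all if config.policy == "all" else cm_unique
    expressed, silent = expressed_silent_partition(cm, config.min_count)
    report["n_expressed"] = len(expressed)
    report["n_silent"] = len(silent)
    diff = differential_repeats(cm, alpha=config.alpha_rna, min_count=config.min_count)
    diff.table["fold_group"] = fold_change_groups(diff.table["delta"].to_numpy())
    _write_tsv(diff.table, out / "repeat_differential.tsv")
    report["n_differential"] = int((diff.table["direction"] != "ns").sum())
    report["n_up"] = int((diff.table["direction"] == "up").sum())
    report["n_down"] = int((diff.table["direction"] == "down").sum())

    enrichment = {}
    for level in ("family", "class"):
        for side in ("up", "down"):
            tab = group_enrichment(diff, fx.annotation, level=level, side=side)
            _write_tsv(tab, out / f"enrichment_{level}_{side}.tsv", index=False)
            if len(tab):
                enrichment[f"{level}_{side}_top"] = {
                    "group": str(tab.iloc[0]["group"]), "q": float(tab.iloc[0]["q"])}
    report["enrichment"] = enrichment

    chip_diff_path = Path(config.out_dir) / "differential.tsv"
    if chip_diff_path.exists():
        chip_tab = pd.read_csv(chip_diff_path, sep="\t", index_col=0)
        from .differential import DifferentialResult
        marks = DifferentialResult(table=chip_tab.drop(columns=["chrom", "start", "end"]),
                                   d0=float("nan"), s0_sq=float("nan"), alpha=config.alpha)
        table, stats_d = locus_mark_fc_table(diff, marks, chip_tab[["chrom", "start", "end"]],
                                             fx.annotation)
        _write_tsv(table, out / "repeat_mark_fc.tsv")
        report["rna_mark_fc_correlation"] = stats_d
    (out / "repeat_report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                       default=_json_default))
    return report
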