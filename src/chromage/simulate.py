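"""Seeded generator of a toy genome with planted age-dependent chromatin.

Emulates the study design the pipeline targets: a small multi-chromosome
genome with repeat-rich arms and a euchromatic center, broad repressive
domains fragmented into called peaks separated by still-enriched gaps,
two ages x two replicates of mark and H3-control counts, planted
aging-specific repressive regions (ASRRs: background mark level when
young, elevated when old), active-mark boundary blurring at old age, and
a multi-copy SINE-like repeat family with ambiguous read mapping and a
planted age-dependent expression increase. A truth manifest records every
planted structure so downstream stages are testable without downloads.

Noise model: counts are marginally negative binomial with the configured
dispersion via a gamma-Poisson hierarchy. The gamma factor represents
biological (chromatin-prep) variation and is shared between the mark IP
and its paired H3 control of the same replicate, so it cancels in
mark/control ratios - the property that makes H3 normalisation work in
the assay being emulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import DataError, GenomeLayout, RegionSet
from .tracks import BinnedTrack, write_bedgraph
from .differential import CountMatrix

# substream tags so each stage draws from an independent, reproducible stream
_STAGE_PLANT, _STAGE_CHIP, _STAGE_TRACKS, _STAGE_REPEATS, _STAGE_LIBRARY = 11, 12, 13, 14, 15


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family: copy number, expression and mapping ambiguity."""

    family: str
    klass: str
    copies: int
    expressed_copies: int
    age_fold: float = 1.0
    ambiguity_group_size: int = 1
    expr_mean: float = 100.0           # expected reads per expressed copy, young
    length_range: tuple[int, int] = (200, 1000)


def default_repeat_families() -> list[RepeatFamilySpec]:
    """Study-condition defaults: a strongly induced, highly ambiguous
    SINE-like family; a mildly induced DNA transposon; stable background
    families; and a silent satellite. Aggregate old/young repeat output
    is ~1.6x."""
    return [
        RepeatFamilySpec("CELE45", "retrotransposon", 60, 40, 4.0, 4, 25.0, (150, 400)),
        RepeatFamilySpec("MARINER3", "DNA transposon", 40, 15, 1.6, 1, 60.0, (800, 1500)),
        RepeatFamilySpec("TIR9", "DNA transposon", 50, 12, 1.0, 1, 150.0, (300, 900)),
        RepeatFamilySpec("LINE2C", "retrotransposon", 30, 8, 1.0, 2, 150.0, (1000, 3000)),
        RepeatFamilySpec("UNKR1", "unknown", 30, 10, 1.0, 1, 150.0, (200, 600)),
        RepeatFamilySpec("SAT35", "satellite", 40, 0, 1.0, 1, 0.0, (100, 300)),
    ]


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chrom: int = 3
    chrom_length: int = 2_000_000
    arm_fraction: float = 0.3
    n_domains: int = 30
    n_asrr: int = 20
    n_background: int = 150
    asrr_fold: float = 2.5
    domain_enrichment: float = 4.0
    depth: float = 200.0               # expected control reads per region per sample
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    blur_fraction: float = 0.5         # fraction of domain edges blurred at old age
    blur_depth: int = 1000             # bp of active-mark intrusion at blurred edges
    track_bin: int = 200
    track_reads_per_bin: float = 50.0
    n_genes: int = 120
    min_separation: int = 10_000
    unplaced_rate: float = 0.02
    rna_repeat_fraction_young: float = 0.05
    repeat_families: list[RepeatFamilySpec] = field(default_factory=default_repeat_families)

    def __post_init__(self) -> None:
        if self.n_chrom <= 0 or self.chrom_length <= 0 or self.n_replicates <= 0:
            raise DataError("counts must be positive")
        if not (0 < self.arm_fraction < 0.5):
            raise DataError("arm_fraction must lie in (0, 0.5)")
        if self.asrr_fold <= 1:
            raise DataError("asrr_fold must exceed 1")
        if self.nb_dispersion < 0:
            raise DataError("nb_dispersion must be >= 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class TruthManifest:
    """Ground truth of every planted structure.

    DataFrames: ``domains`` (id, chrom, start, end, enrichment,
    blurred_left, blurred_right), ``asrrs`` (id, chrom, start, end,
    young_enrichment, old_enrichment), ``background`` (id, chrom, start,
    end), ``genes`` (id, chrom, start, end, region_id, rna_log2fc),
    ``repeat_loci`` (locus, chrom, start, end, strand, family, klass,
    expressed, base_expr, age_fold, group_id). ``rna_total_mapped`` maps
    RNA sample -> total mapped reads.
    """

    domains: pd.DataFrame
    asrrs: pd.DataFrame
    background: pd.DataFrame
    genes: pd.DataFrame
    repeat_loci: pd.DataFrame | None = None
    rna_total_mapped: dict[str, int] = field(default_factory=dict)

    def regions(self) -> pd.DataFrame:
        """All count-matrix features (id, chrom, start, end, kind)."""
        frames = []
        for kind, df in (("domain", self.domains), ("asrr", self.asrrs), ("background", self.background)):
            if len(df):
                sub = df[["id", "chrom", "start", "end"]].copy()
                sub["kind"] = kind
                frames.append(sub)
        if not frames:
            return pd.DataFrame(columns=["id", "chrom", "start", "end", "kind"])
        return pd.concat(frames, ignore_index=True)

    def enrichment(self, kind: str, row: pd.Series, age: str) -> float:
        if kind == "domain":
            return float(row["enrichment"])
        if kind == "asrr":
            return float(row["young_enrichment" if age == "young" else "old_enrichment"])
        return 1.0

    def expected_counts(self, config: SimulationConfig) -> pd.DataFrame:
        """Expected mark/control count per region per ChIP sample."""
        regions = self.regions()
        cols = {}
        for age in ("young", "old"):
            for rep in range(1, config.n_replicates + 1):
                mark = []
                for kind_df, kind in ((self.domains, "domain"), (self.asrrs, "asrr"), (self.background, "background")):
                    for _, row in kind_df.iterrows():
                        mark.append(config.depth * self.enrichment(kind, row, age))
                cols[f"mark_{age}_rep{rep}"] = mark
                cols[f"control_{age}_rep{rep}"] = [config.depth] * len(regions)
        return pd.DataFrame(cols, index=regions["id"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domains": self.domains.to_dict("records"),
            "asrrs": self.asrrs.to_dict("records"),
            "background": self.background.to_dict("records"),
            "genes": self.genes.to_dict("records"),
            "repeat_loci": self.repeat_loci.to_dict("records") if self.repeat_loci is not None else None,
            "rna_total_mapped": self.rna_total_mapped,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        def df(key, cols):
            recs = payload.get(key)
            return pd.DataFrame(recs) if recs else pd.DataFrame(columns=cols)
        return cls(
            domains=df("domains", ["id", "chrom", "start", "end", "enrichment", "blurred_left", "blurred_right"]),
            asrrs=df("asrrs", ["id", "chrom", "start", "end", "young_enrichment", "old_enrichment"]),
            background=df("background", ["id", "chrom", "start", "end"]),
            genes=df("genes", ["id", "chrom", "start", "end", "region_id", "rna_log2fc"]),
            repeat_loci=pd.DataFrame(payload["repeat_loci"]) if payload.get("repeat_loci") else None,
            rna_total_mapped={k: int(v) for k, v in (payload.get("rna_total_mapped") or {}).items()},
        )


def make_layout(config: SimulationConfig) -> GenomeLayout:
    """Toy genome: each chromosome gets two arm compartments and a center."""
    lengths = {}
    comps = {}
    for i in range(config.n_chrom):
        name = f"chr{_roman(i + 1)}"
        L = config.chrom_length
        lengths[name] = L
        a = int(config.arm_fraction * L)
        comps[name] = [(0, a, "arm"), (a, L - a, "center"), (L - a, L, "arm")]
    return GenomeLayout(lengths, comps)


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if n <= len(numerals) else str(n)


def _place(rng, layout: GenomeLayout, width: int, prefer: str | None, prefer_p: float,
           occupied: dict[str, list[tuple[int, int]]], min_sep: int, tries: int = 600) -> tuple[str, int]:
    """Place one interval, preferring a compartment type, keeping min_sep
    from everything already placed."""
    for _ in range(tries):
        chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
        comps = layout.compartments[chrom]
        if prefer is not None and rng.random() < prefer_p:
            cand = [c for c in comps if c[2] == prefer]
        else:
            cand = [c for c in comps if c[2] != prefer] if prefer is not None else comps
        cand = [c for c in cand if c[1] - c[0] > width]
        if not cand:
            continue
        s, e, _lab = cand[rng.integers(len(cand))]
        start = int(rng.integers(s, e - width))
        ok = all(start - min_sep >= oe or start + width + min_sep <= os
                 for os, oe in occupied.get(chrom, []))
        if ok:
            occupied.setdefault(chrom, []).append((start, start + width))
            return chrom, start
    raise DataError("infeasible packing: reduce feature number or size")


def plant_structures(layout: GenomeLayout, config: SimulationConfig) -> TruthManifest:
    """Place constitutive domains, ASRRs, background regions and genes."""
    rng = config.rng(_STAGE_PLANT)
    occupied: dict[str, list[tuple[int, int]]] = {}

    dom_rows = []
    for i in range(config.n_domains):
        width = int(rng.integers(20_000, 50_001))
        chrom, start = _place(rng, layout, width, "arm", 0.8, occupied, config.min_separation)
        dom_rows.append({"id": f"dom_{i:04d}", "chrom": chrom, "start": start,
                         "end": start + width, "enrichment": config.domain_enrichment,
                         "blurred_left": bool(rng.random() < config.blur_fraction),
                         "blurred_right": bool(rng.random() < config.blur_fraction)})
    asrr_rows = []
    for i in range(config.n_asrr):
        width = int(rng.integers(5_000, 15_001))
        chrom, start = _place(rng, layout, width, "center", 0.7, occupied, config.min_separation)
        asrr_rows.append({"id": f"asrr_{i:04d}", "chrom": chrom, "start": start,
                          "end": start + width, "young_enrichment": 1.0,
                          "old_enrichment": config.asrr_fold})
    bg_rows = []
    for i in range(config.n_background):
        width = int(rng.integers(2_000, 6_001))
        chrom, start = _place(rng, layout, width, None, 0.0, occupied, config.min_separation)
        bg_rows.append({"id": f"bg_{i:04d}", "chrom": chrom, "start": start, "end": start + width})

    gene_rows = []
    n_asrr_genes = min(config.n_asrr, config.n_genes // 2) if config.n_asrr else 0
    for i in range(config.n_genes):
        if i < n_asrr_genes:
            a = asrr_rows[i % len(asrr_rows)]
            width = min(int(rng.integers(1_000, 4_001)), a["end"] - a["start"])
            start = int(rng.integers(a["start"], a["end"] - width + 1))
            fc = -0.8 * math.log2(a["old_enrichment"]) + rng.normal(0, 0.3)
            gene_rows.append({"id": f"gene_{i:04d}", "chrom": a["chrom"], "start": start,
                              "end": start + width, "region_id": a["id"],
                              "rna_log2fc": float(fc)})
        else:
            width = int(rng.integers(1_000, 4_001))
            chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
            start = int(rng.integers(0, layout.length(chrom) - width))
            gene_rows.append({"id": f"gene_{i:04d}", "chrom": chrom, "start": start,
                              "end": start + width, "region_id": None,
                              "rna_log2fc": float(rng.normal(0, 0.4))})

    def mk(rows, cols):
        return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    return TruthManifest(
        domains=mk(dom_rows, ["id", "chrom", "start", "end", "enrichment", "blurred_left", "blurred_right"]),
        asrrs=mk(asrr_rows, ["id", "chrom", "start", "end", "young_enrichment", "old_enrichment"]),
        background=mk(bg_rows, ["id", "chrom", "start", "end"]),
        genes=mk(gene_rows, ["id", "chrom", "start", "end", "region_id", "rna_log2fc"]),
    )


def _nb_draw(rng, mean: np.ndarray, dispersion: float, shared_u: np.ndarray | None = None) -> np.ndarray:
    """Gamma-Poisson draw, marginally NB(mean, dispersion).

    ``shared_u`` supplies the gamma factor when it is shared with a
    paired sample; dispersion 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    u = shared_u if shared_u is not None else rng.gamma(1.0 / dispersion, dispersion, size=mean.shape)
    return rng.poisson(mean * u)


def chip_sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for assay in ("mark", "control"):
        for age in ("young", "old"):
            for rep in range(1, config.n_replicates + 1):
                rows.append({"sample_id": f"{assay}_{age}_rep{rep}", "age": age,
                             "assay": assay, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_chip_counts(
    manifest: TruthManifest,
    layout: GenomeLayout,
    config: SimulationConfig,
    library_factors: dict[str, float] | None = None,
) -> tuple[CountMatrix, dict[tuple[str, str, int], BinnedTrack], RegionSet]:
    """Region counts, per-sample coverage tracks and fragmented peak calls.

    Returns (count matrix, tracks keyed (assay, age, rep) with assay in
    {mark, control, active}, fragmented peaks). The biological gamma
    factor of each (region, age, replicate) is shared between the mark
    and control counts of that replicate.
    """
    rng = config.rng(_STAGE_CHIP)
    library_factors = library_factors or {}
    regions = manifest.regions()
    meta = chip_sample_table(config)
    expected = manifest.expected_counts(config)

    counts = pd.DataFrame(0, index=pd.Index(regions["id"], name="feature_id"),
                          columns=list(meta.index), dtype=np.int64)
    disp = config.nb_dispersion
    n_feat = len(regions)
    for age in ("young", "old"):
        for rep in range(1, config.n_replicates + 1):
            if disp > 0:
                u = rng.gamma(1.0 / disp, disp, size=n_feat)
            else:
                u = None
            for assay in ("mark", "control"):
                sid = f"{assay}_{age}_rep{rep}"
                lf = float(library_factors.get(sid, 1.0))
                mu = expected[sid].to_numpy(float) * lf
                counts[sid] = _nb_draw(rng, mu, disp, shared_u=u)
    lib_sizes = (counts.sum(axis=0) * 5).astype(float)
    features = regions.set_index("id")[["chrom", "start", "end", "kind"]]
    features.index.name = "feature_id"
    cm = CountMatrix(counts, meta, features, lib_sizes)

    tracks = _simulate_tracks(manifest, layout, config)
    peaks = _fragment_peaks(manifest, config)
    return cm, tracks, peaks


def _region_bins(start: int, end: int, bin_size: int) -> slice:
    return slice(start // bin_size, math.ceil(end / bin_size))


def _simulate_tracks(manifest: TruthManifest, layout: GenomeLayout,
                     config: SimulationConfig) -> dict[tuple[str, str, int], BinnedTrack]:
    rng = config.rng(_STAGE_TRACKS)
    bs = config.track_bin
    # smooth multiplicative baseline shared by every sample (nucleosome
    # density / mappability landscape); cancels in mark/control ratios
    baseline: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = math.ceil(layout.length(chrom) / bs)
        z = rng.normal(0, 1, n)
        w = 25
        kernel = np.ones(w) / w
        zs = np.convolve(z, kernel, mode="same")
        sd = zs.std() or 1.0
        baseline[chrom] = np.exp(0.5 * zs / sd)

    # per-age enrichment profiles
    enr = {age: {c: np.ones(len(baseline[c])) for c in baseline} for age in ("young", "old")}
    act = {age: {c: np.full(len(baseline[c]), 3.0) for c in baseline} for age in ("young", "old")}
    for _, row in manifest.domains.iterrows():
        sl = _region_bins(int(row["start"]), int(row["end"]), bs)
        for age in ("young", "old"):
            enr[age][row["chrom"]][sl] = config.domain_enrichment
            act[age][row["chrom"]][sl] = 0.3
        blur_bins = max(1, config.blur_depth // bs)
        if row["blurred_left"]:
            b0 = int(row["start"]) // bs
            act["old"][row["chrom"]][b0:b0 + blur_bins] = 2.0
        if row["blurred_right"]:
            b1 = math.ceil(int(row["end"]) / bs)
            act["old"][row["chrom"]][max(b1 - blur_bins, 0):b1] = 2.0
    for _, row in manifest.asrrs.iterrows():
        sl = _region_bins(int(row["start"]), int(row["end"]), bs)
        enr["young"][row["chrom"]][sl] = float(row["young_enrichment"])
        enr["old"][row["chrom"]][sl] = float(row["old_enrichment"])
        for age in ("young", "old"):
            act[age][row["chrom"]][sl] = 0.3

    rate = config.track_reads_per_bin
    tracks: dict[tuple[str, str, int], BinnedTrack] = {}
    for age in ("young", "old"):
        for rep in range(1, config.n_replicates + 1):
            for assay in ("mark", "control", "active"):
                values = {}
                for chrom in layout.chrom_names:
                    b = baseline[chrom]
                    if assay == "mark":
                        mu = rate * b * enr[age][chrom]
                    elif assay == "active":
                        mu = rate * b * act[age][chrom]
                    else:
                        mu = rate * b
                    values[chrom] = rng.poisson(mu).astype(float)
                tracks[(assay, age, rep)] = BinnedTrack(layout, bs, values, None, kind="coverage")
    return tracks


def _fragment_peaks(manifest: TruthManifest, config: SimulationConfig) -> RegionSet:
    """Split each planted region into called-peak fragments.

    Interior gaps are 0.6-4.4 kb (all below the 5 kb merge threshold) and
    remain signal-enriched, so merging reconstructs the planted regions
    exactly; distinct planted regions are >= min_separation apart.
    """
    rng = config.rng(_STAGE_CHIP + 100)
    rows = []
    regions = pd.concat([manifest.domains[["id", "chrom", "start", "end"]],
                         manifest.asrrs[["id", "chrom", "start", "end"]]], ignore_index=True) \
        if len(manifest.domains) or len(manifest.asrrs) else pd.DataFrame(columns=["id", "chrom", "start", "end"])
    for _, row in regions.iterrows():
        start, end = int(row["start"]), int(row["end"])
        width = end - start
        n_gaps = width // 15_000
        if n_gaps == 0:
            rows.append({"chrom": row["chrom"], "start": start, "end": end, "name": f"{row['id']}_p0"})
            continue
        gap_lens = rng.integers(600, 4401, size=n_gaps)
        total_frag = width - int(gap_lens.sum())
        n_frag = n_gaps + 1
        min_frag = 1500
        extra = total_frag - min_frag * n_frag
        if extra < 0:
            rows.append({"chrom": row["chrom"], "start": start, "end": end, "name": f"{row['id']}_p0"})
            continue
        parts = rng.multinomial(extra, np.full(n_frag, 1.0 / n_frag))
        frag_lens = min_frag + parts
        pos = start
        for k in range(n_frag):
            rows.append({"chrom": row["chrom"], "start": pos, "end": pos + int(frag_lens[k]),
                         "name": f"{row['id']}_p{k}"})
            pos += int(frag_lens[k])
            if k < n_gaps:
                pos += int(gap_lens[k])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return RegionSet(df, label="fragmented_peaks")


# ---- repeat RNA ---------------------------------------------------------


def rna_sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for age in ("young", "old"):
        for rep in range(1, config.n_replicates + 1):
            rows.append({"sample_id": f"rna_{age}_rep{rep}", "age": age,
                         "assay": "rna", "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_repeat_reads(
    layout: GenomeLayout,
    manifest: TruthManifest,
    config: SimulationConfig,
):
    """Repeat annotation, read-to-locus placements, and truth additions.

    Reads from an expressed locus map ambiguously to every member of the
    locus's ambiguity group (emulating SINE sequence similarity); silent
    loci emit no reads; a configured fraction of reads is unplaced.
    Returns (RepeatAnnotation, placements DataFrame, manifest).
    """
    from .repeats import RepeatAnnotation

    if not config.repeat_families:
        raise DataError("repeat_families is empty")
    rng = config.rng(_STAGE_REPEATS)
    occupied: dict[str, list[tuple[int, int]]] = {}
    locus_rows = []
    for fam in config.repeat_families:
        order = rng.permutation(fam.copies)
        g = max(1, fam.ambiguity_group_size)
        group_of = {int(order[i]): i // g for i in range(fam.copies)}
        expressed = {int(order[i]) for i in range(min(fam.expressed_copies, fam.copies))}
        for i in range(fam.copies):
            width = int(rng.integers(fam.length_range[0], fam.length_range[1] + 1))
            for _ in range(500):
                chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
                start = int(rng.integers(0, layout.length(chrom) - width))
                if all(start >= oe or start + width <= os for os, oe in occupied.get(chrom, [])):
                    occupied.setdefault(chrom, []).append((start, start + width))
                    break
            else:
                raise DataError("could not place repeat locus")
            base = float(fam.expr_mean * rng.lognormal(0, 0.25)) if i in expressed else 0.0
            locus_rows.append({
                "locus": f"{fam.family}_{i:04d}", "chrom": chrom, "start": start,
                "end": start + width, "strand": "+" if rng.random() < 0.5 else "-",
                "family": fam.family, "klass": fam.klass,
                "expressed": i in expressed, "base_expr": base,
                "age_fold": fam.age_fold, "group_id": f"{fam.family}_g{group_of[i]:03d}",
            })
    loci = pd.DataFrame(locus_rows)
    annotation = RepeatAnnotation(loci[["locus", "chrom", "start", "end", "strand", "family", "klass"]].copy())

    groups = loci.groupby("group_id")["locus"].apply(list).to_dict()
    samples = rna_sample_table(config)
    disp = config.nb_dispersion
    read_rows = []
    expected_young_placed = float(loci.loc[loci["expressed"], "base_expr"].sum())
    total_mapped = int(round(expected_young_placed / config.rna_repeat_fraction_young))
    rna_total_mapped = {}
    for sid, srow in samples.iterrows():
        fold = np.where(srow["age"] == "old", loci["age_fold"].to_numpy(), 1.0)
        mu = loci["base_expr"].to_numpy() * fold
        cnt = _nb_draw(rng, mu, disp)
        counter = 0
        for locus, gid, c in zip(loci["locus"], loci["group_id"], cnt):
            if c <= 0:
                continue
            members = groups[gid]
            match = ",".join(sorted(members)) if len(members) > 1 else locus
            for _ in range(int(c)):
                read_rows.append({"read": f"{sid}:r{counter:06d}", "sample": sid, "loci": match})
                counter += 1
        placed = counter
        intended = int(round(placed / (1.0 - config.unplaced_rate))) if config.unplaced_rate > 0 else placed
        n_unplaced = int(rng.binomial(intended, config.unplaced_rate)) if config.unplaced_rate > 0 else 0
        for k in range(n_unplaced):
            read_rows.append({"read": f"{sid}:u{k:06d}", "sample": sid, "loci": ""})
        rna_total_mapped[sid] = total_mapped
    placements = pd.DataFrame(read_rows, columns=["read", "sample", "loci"])
    manifest.repeat_loci = loci
    manifest.rna_total_mapped = rna_total_mapped
    return annotation, placements, manifest


# ---- association library -----------------------------------------------


def make_association_library(
    manifest: TruthManifest,
    layout: GenomeLayout,
    config: SimulationConfig,
    n_random_sets: int = 5,
) -> dict[str, RegionSet]:
    """A screening library: one profile co-located with the planted ASRRs
    (emulating an H3K9me2-like larval mark) plus random decoy profiles."""
    rng = config.rng(_STAGE_LIBRARY)
    library: dict[str, RegionSet] = {}
    if len(manifest.asrrs):
        rows = []
        for _, a in manifest.asrrs.iterrows():
            jit = int(rng.integers(-500, 501))
            s = max(0, int(a["start"]) + jit)
            e = min(layout.length(a["chrom"]), int(a["end"]) + jit)
            rows.append({"chrom": a["chrom"], "start": s, "end": e})
        for _ in range(30):
            chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
            w = int(rng.integers(2_000, 10_001))
            s = int(rng.integers(0, layout.length(chrom) - w))
            rows.append({"chrom": chrom, "start": s, "end": s + w})
        library["K9me2_L3_like"] = RegionSet(pd.DataFrame(rows), label="K9me2_L3_like")
    for j in range(n_random_sets):
        rows = []
        for _ in range(40):
            chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
            w = int(rng.integers(2_000, 10_001))
            s = int(rng.integers(0, layout.length(chrom) - w))
            rows.append({"chrom": chrom, "start": s, "end": s + w})
        label = f"random_{j + 1}"
        library[label] = RegionSet(pd.DataFrame(rows), label=label)
    return library


# ---- convenience generators for calibration suites ----------------------


def simulate_null_chip_counts(n_features: int, config: SimulationConfig | None = None,
                              seed: int | None = None) -> CountMatrix:
    """Count matrix with no planted age effect (type-I-error suites)."""
    config = config or SimulationConfig()
    if seed is not None:
        rng = np.random.default_rng(seed)
    else:
        rng = config.rng(_STAGE_CHIP + 1)
    meta = chip_sample_table(config)
    counts = pd.DataFrame(0, index=pd.Index([f"f{i:05d}" for i in range(n_features)], name="feature_id"),
                          columns=list(meta.index), dtype=np.int64)
    disp = config.nb_dispersion
    for age in ("young", "old"):
        for rep in range(1, config.n_replicates + 1):
            u = rng.gamma(1.0 / disp, disp, size=n_features) if disp > 0 else None
            for assay in ("mark", "control"):
                counts[f"{assay}_{age}_rep{rep}"] = _nb_draw(
                    rng, np.full(n_features, config.depth), disp, shared_u=u)
    features = pd.DataFrame({"chrom": "chrI", "start": 0, "end": 1000}, index=counts.index)
    lib = (counts.sum(axis=0) * 5).astype(float)
    return CountMatrix(counts, meta, features, lib)


# ---- fixture writing -----------------------------------------------------


def write_fixture(directory: str | Path, config: SimulationConfig | None = None,
                  overwrite: bool = False) -> Path:
    """Run every simulation stage and write the full fixture to disk.

    Emits chrom.sizes, compartments.bed, peaks.bed, per-sample bedGraph
    tracks, count/metadata TSVs, repeat annotation/placement TSVs, the
    association library and truth.json. Re-running with the same config
    reproduces byte-identical files.
    """
    from .genome import write_bed

    config = config or SimulationConfig()
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise DataError(f"{directory} is not empty (pass overwrite=True)")
    (directory / "tracks").mkdir(parents=True, exist_ok=True)
    (directory / "assoc_library").mkdir(exist_ok=True)

    layout = make_layout(config)
    manifest = plant_structures(layout, config)
    cm, tracks, peaks = simulate_chip_counts(manifest, layout, config)
    annotation, placements, manifest = simulate_repeat_reads(layout, manifest, config)
    library = make_association_library(manifest, layout, config)

    layout.to_files(directory / "chrom.sizes", directory / "compartments.bed")
    write_bed(peaks, directory / "peaks.bed")
    out_counts = cm.features[["chrom", "start", "end"]].join(cm.counts)
    out_counts.to_csv(directory / "chip_counts.tsv", sep="\t")
    meta = cm.samples.copy()
    meta["library_size"] = cm.library_sizes.astype(int)
    meta.to_csv(directory / "chip_samples.tsv", sep="\t")
    for (assay, age, rep), track in sorted(tracks.items()):
        write_bedgraph(track, directory / "tracks" / f"{assay}_{age}_rep{rep}.bedgraph")
    annotation.to_tsv(directory / "repeat_annotation.tsv")
    placements.to_csv(directory / "repeat_placements.tsv", sep="\t", index=False)
    rna_meta = rna_sample_table(config)
    rna_meta["total_mapped"] = pd.Series(manifest.rna_total_mapped)
    rna_meta.to_csv(directory / "rna_samples.tsv", sep="\t")
    for label, rs in sorted(library.items()):
        write_bed(rs, directory / "assoc_library" / f"{label}.bed")
    manifest.to_json(directory / "truth.json")
    (directory / "config.json").write_text(json.dumps(
        {k: v for k, v in asdict(config).items() if k != "repeat_families"}
        | {"repeat_families": [asdict(f) for f in config.repeat_families]},
        indent=1, sort_keys=True))
    return directory
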