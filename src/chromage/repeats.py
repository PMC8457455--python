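"""Locus-level repetitive-element expression analysis.

Repeat-derived RNA reads often align equally well to several copies of
a family (SINEs especially). Two counting policies are supported:
``all`` assigns one count to every matched locus (multi-mapper aware),
``unique`` counts only reads matching a single locus. Downstream:
transcriptome fraction bookkeeping, differential expression via the
shared moderated-t engine, and class/family over-representation by the
hypergeometric test with expressed loci as the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import CountMatrix, DifferentialResult, bh_adjust, differential_expression
from .genome import DataError

REPEAT_CLASSES = ("DNA transposon", "retrotransposon", "satellite", "unknown")


@dataclass
class RepeatAnnotation:
    """Repeat loci with family and class labels.

    ``table`` columns: locus (unique id), chrom, start, end, strand,
    family, klass (one of REPEAT_CLASSES).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"locus", "chrom", "start", "end", "family", "klass"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        if t["locus"].duplicated().any():
            raise DataError("duplicate locus ids in annotation")
        if "strand" not in t.columns:
            t["strand"] = "."
        bad = ~t["klass"].isin(REPEAT_CLASSES)
        if bad.any():
            raise DataError(f"unknown repeat class: {sorted(t.loc[bad, 'klass'].unique())}")
        self.table = t.reset_index(drop=True)

    @property
    def loci(self) -> pd.Index:
        return pd.Index(self.table["locus"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RepeatAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


def categorize_placements(placements: pd.DataFrame) -> pd.Series:
    """unique (1 locus), multi (>1) or unplaced (0) per read row."""
    n_loci = placements["loci"].map(lambda s: 0 if not s else len(s.split(",")))
    return pd.Series(np.where(n_loci == 0, "unplaced", np.where(n_loci == 1, "unique", "multi")),
                     index=placements.index, name="category")


def read_placements(path: str | Path) -> pd.DataFrame:
    """Read a placements TSV (read, sample, comma-separated loci; empty = unplaced)."""
    df = pd.read_csv(path, sep="\t", dtype={"read": str, "sample": str, "loci": str})
    df["loci"] = df["loci"].fillna("")
    return df


def count_repeat_reads(
    placements: pd.DataFrame,
    annotation: RepeatAnnotation,
    sample_meta: pd.DataFrame,
    policy: str = "all",
    total_mapped: pd.Series | None = None,
) -> CountMatrix:
    """Per-locus count matrix under a multi-mapper policy.

    ``all``: each read adds 1 to every matched locus. ``unique``: only
    reads matching exactly one locus are counted. Library sizes are the
    per-sample transcriptome totals when ``total_mapped`` is given
    (depth normalisation should be against the whole transcriptome, not
    the repeat compartment, whose output genuinely shifts with age);
    otherwise the number of distinct placed reads.
    """
    if policy not in ("all", "unique"):
        raise DataError(f"policy must be 'all' or 'unique', got {policy!r}")
    loci = annotation.loci
    locus_pos = {l: i for i, l in enumerate(loci)}
    samples = list(sample_meta.index)
    sample_pos = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(loci), len(samples)), dtype=np.int64)
    placed_reads = np.zeros(len(samples), dtype=np.int64)
    for row in placements.itertuples(index=False):
        if row.sample not in sample_pos:
            raise DataError(f"sample {row.sample} missing from metadata")
        j = sample_pos[row.sample]
        ids = [x for x in str(row.loci).split(",") if x] if row.loci else []
        if not ids:
            continue
        placed_reads[j] += 1
        if policy == "unique" and len(ids) > 1:
            continue
        for lid in ids:
            if lid not in locus_pos:
                raise DataError(f"unknown locus id {lid!r} in placements")
            counts[locus_pos[lid], j] += 1
    features = annotation.table.set_index("locus")[["chrom", "start", "end"]]
    if total_mapped is not None:
        lib = total_mapped.reindex(samples).astype(float)
    else:
        lib = pd.Series(placed_reads, index=samples, dtype=float)
    # under 'all' the locus-inflated column sum can exceed the distinct-read
    # total; keep the larger to satisfy the count-matrix invariant
    lib = np.maximum(lib, counts.sum(axis=0))
    cm = CountMatrix(pd.DataFrame(counts, index=features.index, columns=samples),
                     sample_meta.copy(), features, lib)
    cm.counts.attrs["placed_reads"] = pd.Series(placed_reads, index=samples)
    return cm


def repeat_fraction(
    placements: pd.DataFrame,
    total_mapped: pd.Series,
    sample_ages: pd.Series,
) -> tuple[pd.Series, float, float]:
    """Fraction of mapped RNA reads that are repeat-derived, per sample.

    Computed on distinct placed reads (a multi-mapped read counts once),
    so the fraction stays in [0, 1]. Returns (fractions, t, p) where the
    t-test compares old vs young replicate fractions (two-tailed).
    """
    cat = categorize_placements(placements)
    placed = placements[cat != "unplaced"].groupby("sample").size()
    fractions = {}
    for sample in total_mapped.index:
        total = float(total_mapped[sample])
        if total <= 0:
            raise DataError(f"zero total mapped reads for {sample}")
        n = float(placed.get(sample, 0))
        if n > total:
            raise DataError(f"repeat reads exceed total mapped for {sample}")
        fractions[sample] = n / total
    frac = pd.Series(fractions, name="repeat_fraction")
    young = frac[sample_ages.reindex(frac.index) == "young"]
    old = frac[sample_ages.reindex(frac.index) == "old"]
    if len(young) >= 2 and len(old) >= 2:
        t, p = stats.ttest_ind(old, young)
        return frac, float(t), float(p)
    return frac, float("nan"), float("nan")


def unmapped_fraction(placements: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of reads that matched no locus."""
    cat = categorize_placements(placements)
    total = placements.groupby("sample").size()
    unplaced = placements[cat == "unplaced"].groupby("sample").size()
    return (unplaced.reindex(total.index).fillna(0) / total).rename("unmapped_fraction")


def expressed_silent_partition(cm: CountMatrix, min_count: int = 5) -> tuple[pd.Index, pd.Index]:
    """Split loci into expressed (>= min_count in >= 1 sample) and silent."""
    expressed_mask = (cm.counts >= min_count).any(axis=1)
    return cm.counts.index[expressed_mask], cm.counts.index[~expressed_mask]


def differential_repeats(cm: CountMatrix, alpha: float = 0.01, min_count: int = 5) -> DifferentialResult:
    """Differential expression over expressed loci (silent loci excluded)."""
    expressed, _silent = expressed_silent_partition(cm, min_count)
    return differential_expression(cm.subset_features(expressed), alpha=alpha)


def group_enrichment(
    diff: DifferentialResult,
    annotation: RepeatAnnotation,
    level: str = "family",
    side: str = "up",
    low_power_k: int = 5,
) -> pd.DataFrame:
    """Class/family over-representation among differential loci.

    For each group: hypergeometric upper-tail probability of drawing k
    group members among the n differential loci from the N expressed
    loci of which K belong to the group. BH across groups at the chosen
    level. Groups with K < ``low_power_k`` are flagged but still tested.
    """
    if level not in ("family", "klass", "class"):
        raise DataError("level must be 'family' or 'class'")
    col = "family" if level == "family" else "klass"
    if side not in ("up", "down"):
        raise DataError("side must be 'up' or 'down'")
    ann = annotation.table.set_index("locus")
    tested = diff.table.index
    groups = ann.loc[ann.index.intersection(tested), col]
    N = len(groups)
    diff_loci = diff.table.index[diff.table["direction"] == side]
    n = len(diff_loci)
    rows = []
    for group, members in groups.groupby(groups):
        K = len(members)
        k = int(diff_loci.isin(members.index).sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        rows.append({"group": group, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0), "low_power": K < low_power_k})
    df = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "group"]).reset_index(drop=True)
    return df


def locus_mark_fc_table(
    diff_repeats: DifferentialResult,
    diff_marks: DifferentialResult,
    mark_features: pd.DataFrame,
    annotation: RepeatAnnotation,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join per-locus RNA fold change with the overlapping peak's mark change.

    ``mark_features`` gives chrom/start/end per mark feature id. A locus
    overlapping several differential peaks takes the peak with largest
    absolute effect. Loci with no overlapping peak carry NaN mark delta.
    Returns (table, {"pearson_r": r}); r is NaN when < 3 paired loci.
    """
    ann = annotation.table.set_index("locus")
    mark = diff_marks.table.join(mark_features[["chrom", "start", "end"]])
    rows = []
    for locus in diff_repeats.table.index:
        info = ann.loc[locus]
        hits = mark[(mark["chrom"] == info["chrom"]) &
                    (mark["start"] < info["end"]) & (mark["end"] > info["start"])]
        if len(hits):
            best = hits.loc[hits["delta"].abs().idxmax()]
            mark_delta = float(best["delta"])
        else:
            mark_delta = float("nan")
        rows.append({"locus": locus, "family": info["family"], "klass": info["klass"],
                     "rna_delta": float(diff_repeats.table.loc[locus, "delta"]),
                     "mark_delta": mark_delta})
    table = pd.DataFrame(rows).set_index("locus")
    paired = table.dropna(subset=["mark_delta"])
    if len(paired) >= 3 and paired["rna_delta"].std() > 0 and paired["mark_delta"].std() > 0:
        r = float(stats.pearsonr(paired["rna_delta"], paired["mark_delta"])[0])
    else:
        r = float("nan")
    return table, {"pearson_r": r, "n_paired": float(len(paired))}
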