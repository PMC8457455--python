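"""Region-level differential enrichment for the two-age double contrast.

The core statistic mirrors the (mark - control)_old - (mark - control)_young
contrast: per age and replicate, a depth-normalised log2 mark/control
ratio R is formed, the age effect is Delta = mean_old(R) - mean_young(R),
and a moderated t-test with empirical-Bayes variance shrinkage (limma-style
log-scale moment estimator) assesses it. BH controls the FDR; regions that
gain the mark with age while lacking it at the young time point are
classified as aging-specific repressive regions (ASRRs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genome import DataError


@dataclass
class CountMatrix:
    """Features x samples read counts with sample metadata.

    ``samples`` has one row per sample with columns sample_id, age
    (young|old), assay (mark|control|rna), replicate. ``features`` has
    one row per feature with columns feature_id, chrom, start, end.
    ``library_sizes`` maps sample_id -> total mapped reads (>= column sum).
    """

    counts: pd.DataFrame            # index: feature_id, columns: sample_id
    samples: pd.DataFrame           # index: sample_id
    features: pd.DataFrame          # index: feature_id
    library_sizes: pd.Series        # index: sample_id

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        missing = self.samples[["age", "assay", "replicate"]].isna().any(axis=1)
        if missing.any():
            raise DataError(f"samples missing metadata: {list(self.samples.index[missing])}")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        colsums = self.counts.sum(axis=0)
        lib = self.library_sizes.loc[self.counts.columns]
        if (lib < colsums - 1e-9).any():
            raise DataError("library_sizes must be >= column sums")

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[ids], self.samples, self.features.loc[ids], self.library_sizes)


def count_reads_in_regions(placements: pd.DataFrame, regions, sample_meta: pd.DataFrame,
                           library_sizes: pd.Series | None = None) -> CountMatrix:
    """Count reads into regions by 5' end membership (half-open).

    ``placements`` needs columns chrom/start/end/sample (optionally
    strand); each read counts toward a region iff its 5' end lies in
    [start, end), at most once per sample.
    """
    if "sample" not in placements.columns:
        raise DataError("placements must carry a 'sample' column")
    unknown = set(placements["sample"]) - set(sample_meta.index)
    if unknown:
        raise DataError(f"samples missing metadata: {sorted(unknown)}")
    feat_rows = []
    ids = []
    for i, row in enumerate(regions.df.itertuples(index=False)):
        fid = row.name if not pd.isna(row.name) else f"region_{i:05d}"
        ids.append(fid)
        feat_rows.append({"feature_id": fid, "chrom": row.chrom, "start": row.start, "end": row.end})
    features = pd.DataFrame(feat_rows).set_index("feature_id") if feat_rows else pd.DataFrame(
        columns=["chrom", "start", "end"]).rename_axis("feature_id")
    counts = pd.DataFrame(0, index=features.index, columns=list(sample_meta.index))
    if len(placements) and len(features):
        strand = placements["strand"] if "strand" in placements.columns else pd.Series(".", index=placements.index)
        five = np.where(strand.to_numpy() == "-", placements["end"].to_numpy(np.int64) - 1,
                        placements["start"].to_numpy(np.int64))
        pl = placements.assign(_five=five)
        for chrom in regions.chroms:
            sub_f = features[features["chrom"] == chrom]
            starts = sub_f["start"].to_numpy(np.int64)
            ends = sub_f["end"].to_numpy(np.int64)
            sub_p = pl[pl["chrom"] == chrom]
            if not len(sub_p) or not len(sub_f):
                continue
            for sample, grp in sub_p.groupby("sample"):
                p5 = grp["_five"].to_numpy(np.int64)
                # regions may overlap in principle; loop regions (few) over reads
                for fid, s, e in zip(sub_f.index, starts, ends):
                    counts.loc[fid, sample] += int(((p5 >= s) & (p5 < e)).sum())
    if library_sizes is None:
        library_sizes = placements.groupby("sample").size().reindex(sample_meta.index).fillna(0).astype(float)
        library_sizes = np.maximum(library_sizes, counts.sum(axis=0))
    return CountMatrix(counts.astype(np.int64), sample_meta.copy(), features, pd.Series(library_sizes))


# ---- normalised log ratios --------------------------------------------


def normalized_log_ratio(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Depth-normalised mark-over-control log2 ratio per (age, replicate).

    R = log2((k_mark + c) / N_mark) - log2((k_ctrl + c) / N_ctrl), pairing
    mark and control samples within each age by replicate id. Returns a
    features x pairs DataFrame whose columns carry (age, replicate)
    metadata in ``attrs['pairs']``.
    """
    meta = cm.samples
    marks = meta[meta["assay"] == "mark"]
    ctrls = meta[meta["assay"] == "control"]
    pairs = []
    unpaired = []
    for sid, row in marks.iterrows():
        match = ctrls[(ctrls["age"] == row["age"]) & (ctrls["replicate"] == row["replicate"])]
        if len(match) != 1:
            unpaired.append(sid)
        else:
            pairs.append((sid, match.index[0], row["age"], row["replicate"]))
    if unpaired:
        raise DataError(f"mark samples without a unique paired control: {unpaired}")
    if not pairs:
        raise DataError("no mark/control pairs found")
    data = {}
    pair_meta = []
    for mark_id, ctrl_id, age, rep in pairs:
        km = cm.counts[mark_id].to_numpy(float)
        kc = cm.counts[ctrl_id].to_numpy(float)
        nm = float(cm.library_sizes[mark_id])
        nc = float(cm.library_sizes[ctrl_id])
        col = f"{age}_rep{rep}"
        data[col] = np.log2((km + pseudocount) / nm) - np.log2((kc + pseudocount) / nc)
        pair_meta.append({"column": col, "age": age, "replicate": rep})
    R = pd.DataFrame(data, index=cm.counts.index)
    R.attrs["pairs"] = pd.DataFrame(pair_meta)
    return R


def normalized_log_counts(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Depth-normalised log2 counts per sample (no control pairing; RNA)."""
    data = {}
    pair_meta = []
    for sid, row in cm.samples.iterrows():
        k = cm.counts[sid].to_numpy(float)
        n = float(cm.library_sizes[sid])
        data[sid] = np.log2((k + pseudocount) / n)
        pair_meta.append({"column": sid, "age": row["age"], "replicate": row["replicate"]})
    R = pd.DataFrame(data, index=cm.counts.index)
    R.attrs["pairs"] = pd.DataFrame(pair_meta)
    return R


# ---- moderated t machinery ---------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(80):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit of the scaled-F prior for per-feature variances.

    Matches the mean and variance of log(s2) against the theoretical
    moments of log of a scaled F(df, d0) variable, returning (d0, s0_sq).
    d0 = inf means the observed spread of log(s2) is no wider than pure
    chi-square noise and all variances shrink to s0_sq.
    """
    s2 = np.asarray(s2, float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.nanmedian(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2)) + math.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    rhs = e_var - float(special.polygamma(1, df / 2))
    if rhs <= 0:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


@dataclass
class DifferentialResult:
    """Per-feature differential-enrichment table plus fitted prior.

    ``table`` columns: feature_id (index), delta (log2 age effect), s2,
    t_mod, p, q, direction (up|down|ns), young_mean_z (NaN until
    classify_asrr), asrr (bool). ``excluded`` lists all-zero features
    dropped before testing.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    alpha: float
    excluded: list[str] = field(default_factory=list)


def age_contrast_test(R: pd.DataFrame, alpha: float = 0.05,
                      young: str = "young", old: str = "old",
                      robust_center: bool = True) -> DifferentialResult:
    """Moderated-t test of the old-minus-young contrast of log ratios.

    Delta = mean_old(R) - mean_young(R); per-feature variance is pooled
    across the two ages, shrunk toward the fitted prior
    s~2 = (d0*s0^2 + d*s2) / (d0 + d), and t = Delta / (s~ *
    sqrt(1/n_old + 1/n_young)) is referred to a t distribution with
    d0 + d degrees of freedom (two-sided).

    ``robust_center`` subtracts each column's median across features
    first. This is the usual most-features-unchanged normalisation: it
    removes library-composition shifts (a handful of strongly gaining
    regions inflating one library's total) that would otherwise push
    every stable feature slightly in the opposite direction.
    """
    pairs = R.attrs.get("pairs")
    if pairs is None:
        raise DataError("R must carry column metadata in attrs['pairs']")
    y_cols = pairs.loc[pairs["age"] == young, "column"].tolist()
    o_cols = pairs.loc[pairs["age"] == old, "column"].tolist()
    if len(y_cols) < 2 or len(o_cols) < 2:
        raise DataError("need >= 2 replicates per age")
    if robust_center and len(R) >= 10:
        R = R - R.median(axis=0)
        R.attrs["pairs"] = pairs
    Y = R[y_cols].to_numpy(float)
    O = R[o_cols].to_numpy(float)
    n_y, n_o = Y.shape[1], O.shape[1]
    delta = O.mean(axis=1) - Y.mean(axis=1)
    df_resid = float(n_y + n_o - 2)
    ss = Y.var(axis=1, ddof=1) * (n_y - 1) + O.var(axis=1, ddof=1) * (n_o - 1)
    s2 = ss / df_resid
    d0, s0_sq = fit_variance_prior(s2, df_resid)
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = 1e9
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_tilde * (1.0 / n_o + 1.0 / n_y))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    direction = np.where(q < alpha, np.where(delta > 0, "up", "down"), "ns")
    table = pd.DataFrame({
        "delta": delta, "s2": s2, "t_mod": t_mod, "p": p, "q": q,
        "direction": direction,
        "young_mean_z": np.nan, "asrr": False,
    }, index=R.index)
    return DifferentialResult(table=table, d0=d0, s0_sq=s0_sq, alpha=alpha)


def differential_enrichment(cm: CountMatrix, alpha: float = 0.05) -> DifferentialResult:
    """ChIP arm: normalise to mark/control ratios, test, report exclusions."""
    nonzero = cm.counts.sum(axis=1) > 0
    excluded = list(cm.counts.index[~nonzero])
    cm_use = cm.subset_features(cm.counts.index[nonzero]) if excluded else cm
    res = age_contrast_test(normalized_log_ratio(cm_use), alpha=alpha)
    res.excluded = excluded
    return res


def differential_expression(cm: CountMatrix, alpha: float = 0.01) -> DifferentialResult:
    """RNA arm: no control assay; contrast of depth-normalised log counts.

    Median-centering is disabled here: library sizes are whole-transcriptome
    totals, and the tested feature set (e.g. expressed repeat loci) can be
    dominated by genuinely changing features, which would make the
    most-features-unchanged assumption behind robust centering invalid.
    """
    nonzero = cm.counts.sum(axis=1) > 0
    excluded = list(cm.counts.index[~nonzero])
    cm_use = cm.subset_features(cm.counts.index[nonzero]) if excluded else cm
    res = age_contrast_test(normalized_log_counts(cm_use), alpha=alpha,
                            robust_center=False)
    res.excluded = excluded
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_asrr(res: DifferentialResult, young_z: pd.Series, asrr_z_max: float = 0.0) -> DifferentialResult:
    """Flag aging-specific repressive regions.

    ASRR iff the region is significantly up with age AND its young-age
    mean z (from the young mark/control z-score track) is below
    ``asrr_z_max`` — i.e. the region lacked the mark when young.
    """
    missing = res.table.index.difference(young_z.index)
    if len(missing):
        raise DataError(f"young_z missing features: {list(missing[:5])}")
    res.table["young_mean_z"] = young_z.reindex(res.table.index).astype(float)
    res.table["asrr"] = (res.table["direction"] == "up") & (res.table["young_mean_z"] < asrr_z_max)
    return res


def fold_change_groups(delta, bounds: tuple[float, float] = (0.75, 1.25)) -> np.ndarray:
    """Group features by linear fold change 2**delta.

    A: fold > bounds[1]; B: bounds[0] <= fold <= bounds[1]; C: fold <
    bounds[0].
    """
    fold = np.power(2.0, np.asarray(delta, float))
    lo, hi = bounds
    return np.where(fold > hi, "A", np.where(fold < lo, "C", "B"))


# ---- sample-level overview ----------------------------------------------


@dataclass
class MdsEmbedding:
    coords: pd.DataFrame          # samples x (dim1, dim2)
    eigenvalue_fractions: np.ndarray
    degenerate: bool = False


def mds_embed(values: pd.DataFrame, top: int = 500) -> MdsEmbedding:
    """Classical MDS of samples from per-feature values.

    The distance between two samples is the root-mean-square difference
    over the ``top`` features with the largest absolute difference for
    that pair (leading-difference distance), or all features if fewer.
    Classical (Torgerson) MDS: double-centre the squared distances and
    take the top-2 spectral coordinates. Sign convention: the first
    sample has a non-negative coordinate on each axis.
    """
    if values.shape[1] < 3:
        raise DataError("mds_embed needs >= 3 samples")
    X = values.to_numpy(float)
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(X[:, i] - X[:, j])
            if len(diff) > top:
                sel = np.partition(diff, len(diff) - top)[len(diff) - top:]
            else:
                sel = diff
            D[i, j] = D[j, i] = math.sqrt(float((sel ** 2).mean()))
    degenerate = bool(np.allclose(D, 0))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w_pos = np.clip(w, 0, None)
    coords = v[:, :2] * np.sqrt(w_pos[:2])
    for k in range(2):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    tot = w_pos.sum()
    fracs = (w_pos[:2] / tot) if tot > 0 else np.zeros(2)
    cdf = pd.DataFrame(coords, index=values.columns, columns=["dim1", "dim2"])
    return MdsEmbedding(coords=cdf, eigenvalue_fractions=fracs, degenerate=degenerate)


# ---- expression-association statistics ----------------------------------


def rpkm(counts, lengths, library_size: float) -> np.ndarray:
    """Reads per kilobase per million mapped reads: 1e9 * k / (L * N)."""
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if np.any(lengths <= 0):
        raise DataError("feature lengths must be positive")
    if library_size <= 0:
        raise DataError("library size must be positive")
    return 1e9 * counts / (lengths * library_size)


def log2_rpkm(counts, lengths, library_size: float, pseudocount: float = 0.1) -> np.ndarray:
    return np.log2(rpkm(counts, lengths, library_size) + pseudocount)


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample two-sided KS statistic and asymptotic p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    insufficient: bool = False


def fc_correlation(rna_fc, mark_fc) -> CorrelationResult:
    """Pearson correlation between RNA and mark log2 fold changes."""
    rna_fc = np.asarray(rna_fc, float)
    mark_fc = np.asarray(mark_fc, float)
    ok = np.isfinite(rna_fc) & np.isfinite(mark_fc)
    rna_fc, mark_fc = rna_fc[ok], mark_fc[ok]
    if len(rna_fc) < 3:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(rna_fc), insufficient=True)
    if np.std(rna_fc) == 0 or np.std(mark_fc) == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(rna_fc), insufficient=True)
    r, p = stats.pearsonr(rna_fc, mark_fc)
    return CorrelationResult(r=float(r), p=float(p), n=len(rna_fc))
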