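"""Region-set association: windowed coverage correlation + permutation overlap.

Two complementary screens for whether two genomic region sets occupy the
same territory: (1) Pearson correlation of covered bp in genome-tiling
windows, and (2) a permutation test that re-places the query regions
uniformly at random (lengths preserved, chromosome chosen in proportion
to placeable length) and compares the observed count of query regions
overlapping the target against the permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DataError, GenomeLayout, RegionSet, _merge_sorted


def windowed_peak_coverage(regions: RegionSet, layout: GenomeLayout, window: int = 50_000) -> np.ndarray:
    """Covered bp of the region footprint in tiling windows.

    Windows tile each chromosome with step = window (last partial window
    kept); chromosomes concatenate in layout order.
    """
    if window <= 0:
        raise DataError("window must be positive")
    parts = []
    for chrom in layout.chrom_names:
        length = layout.length(chrom)
        n_win = math.ceil(length / window)
        cov = np.zeros(n_win)
        starts, ends = regions.per_chrom(chrom)
        if len(starts):
            ms, me = _merge_sorted(starts, ends)
            for s, e in zip(ms, me):
                w0, w1 = s // window, (e - 1) // window
                for w in range(w0, w1 + 1):
                    lo = max(s, w * window)
                    hi = min(e, (w + 1) * window)
                    cov[w] += hi - lo
        parts.append(cov)
    return np.concatenate(parts)


def profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two coverage vectors; NaN if either is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class AssociationResult:
    query_label: str
    target_label: str
    obs_overlap: int
    null_mean: float
    null_sd: float
    perm_z: float
    perm_p: float
    n_perm: int
    seed: int | None
    pearson_r: float = float("nan")
    null_sd_zero: bool = False


class _TargetIndex:
    """Merged target footprint per chromosome for fast overlap queries."""

    def __init__(self, target: RegionSet, chrom_names: list[str]) -> None:
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom in chrom_names:
            s, e = target.per_chrom(chrom)
            ms, me = _merge_sorted(s, e)
            self.starts[chrom], self.ends[chrom] = ms, me

    def hits(self, chrom_idx: np.ndarray, starts: np.ndarray, widths: np.ndarray,
             chrom_names: list[str]) -> np.ndarray:
        """Boolean array: does each interval overlap the target (>=1 bp)?"""
        out = np.zeros(starts.shape, dtype=bool)
        for ci, chrom in enumerate(chrom_names):
            sel = chrom_idx == ci
            if not sel.any():
                continue
            ts, te = self.starts[chrom], self.ends[chrom]
            if len(ts) == 0:
                continue
            s = starts[sel]
            e = s + widths[sel]
            idx = np.searchsorted(ts, e, side="left")
            hit = (idx > 0) & (te[np.maximum(idx - 1, 0)] > s)
            out[sel] = hit
        return out


def _placement_probs(widths: np.ndarray, chrom_lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-region chromosome sampling CDF and placeable lengths.

    placeable[i, c] = max(L_c - w_i + 1, 0); a region longer than every
    chromosome is an error (checked by the caller).
    """
    placeable = np.maximum(chrom_lengths[None, :] - widths[:, None] + 1, 0).astype(float)
    totals = placeable.sum(axis=1)
    cdf = np.cumsum(placeable, axis=1) / totals[:, None]
    return cdf, placeable


def permutation_overlap_test(
    query: RegionSet,
    target: RegionSet,
    layout: GenomeLayout,
    n_perm: int = 2000,
    seed: int | None = None,
    non_overlapping: bool = True,
    rng: np.random.Generator | None = None,
    max_rounds: int = 2000,
) -> AssociationResult:
    """Permutation test of region-set overlap.

    Statistic: number of query regions overlapping >= 1 bp of the target
    footprint. Null: every query region is re-placed uniformly at random
    on the genome with its length preserved; the chromosome is chosen
    with probability proportional to placeable length. When
    ``non_overlapping``, a permutation whose placements collide is
    rejected and redrawn whole, giving the uniform distribution over
    disjoint configurations. ``perm_p = (1 + #{null >= obs}) / (n_perm +
    1)`` on the tail indicated by the sign of (obs - null mean).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chrom_names = layout.chrom_names
    L = np.array([layout.length(c) for c in chrom_names], dtype=np.int64)
    widths = query.widths()
    n = len(widths)
    if n == 0:
        raise DataError("query region set is empty")
    if np.any(widths > L.max()):
        raise DataError("a query region is longer than every chromosome")
    if non_overlapping and widths.sum() > 0.8 * layout.total_length:
        raise DataError("non-overlapping placement infeasible: query covers most of the genome")
    index = _TargetIndex(target, chrom_names)

    # observed statistic
    obs_chrom = np.array([chrom_names.index(c) for c in query.df["chrom"]])
    obs_starts = query.df["start"].to_numpy(np.int64)
    obs = int(index.hits(obs_chrom, obs_starts, widths, chrom_names).sum())

    cdf, placeable = _placement_probs(widths, L)

    def draw(n_rows: int) -> tuple[np.ndarray, np.ndarray]:
        u = rng.random((n_rows, n))
        chrom_idx = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
        span = placeable[np.arange(n)[None, :], chrom_idx]
        starts = (rng.random((n_rows, n)) * span).astype(np.int64)
        return chrom_idx, starts

    chrom_idx, starts = draw(n_perm)
    if non_overlapping and n > 1:
        key = chrom_idx.astype(np.int64) * (int(L.max()) + 1) + starts
        order = np.argsort(key, axis=1)
        for _ in range(max_rounds):
            sk = np.take_along_axis(key, order, axis=1)
            sc = np.take_along_axis(chrom_idx, order, axis=1)
            ss = np.take_along_axis(starts, order, axis=1)
            sw = widths[order]
            same_chrom = sc[:, 1:] == sc[:, :-1]
            clash = (same_chrom & (ss[:, 1:] < ss[:, :-1] + sw[:, :-1])).any(axis=1)
            if not clash.any():
                break
            n_bad = int(clash.sum())
            ci, st = draw(n_bad)
            chrom_idx[clash], starts[clash] = ci, st
            key[clash] = ci.astype(np.int64) * (int(L.max()) + 1) + st
            order[clash] = np.argsort(key[clash], axis=1)
        else:
            raise DataError("non-overlapping placement did not converge; query too dense")

    null = index.hits(chrom_idx, starts, np.broadcast_to(widths, chrom_idx.shape), chrom_names).sum(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    sd_zero = null_sd == 0
    perm_z = float("nan") if sd_zero else (obs - null_mean) / null_sd
    if obs >= null_mean:
        perm_p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    else:
        perm_p = (1 + int((null <= obs).sum())) / (n_perm + 1)
    return AssociationResult(
        query_label=query.label, target_label=target.label,
        obs_overlap=obs, null_mean=null_mean, null_sd=null_sd,
        perm_z=perm_z, perm_p=perm_p, n_perm=n_perm, seed=seed,
        null_sd_zero=sd_zero,
    )


def rank_associations(
    query: RegionSet,
    library: dict[str, RegionSet],
    layout: GenomeLayout,
    window: int = 50_000,
    n_perm: int = 2000,
    seed: int | None = None,
    r_threshold: float = 0.45,
    z_threshold: float = 34.0,
) -> pd.DataFrame:
    """Dual-statistic screen of a query set against a library of profiles.

    For each target: windowed-coverage Pearson r and permutation z.
    Targets are ranked by the better (minimum) of their two rank
    positions; ``passes_both`` flags targets exceeding both thresholds.
    """
    if not library:
        raise DataError("library is empty")
    qcov = windowed_peak_coverage(query, layout, window)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(library))
    for child, (label, target) in zip(children, sorted(library.items())):
        r = profile_correlation(qcov, windowed_peak_coverage(target, layout, window))
        res = permutation_overlap_test(query, target, layout, n_perm=n_perm,
                                       rng=np.random.default_rng(child))
        rows.append({"target": label, "pearson_r": r, "obs": res.obs_overlap,
                     "null_mean": res.null_mean, "null_sd": res.null_sd,
                     "perm_z": res.perm_z, "perm_p": res.perm_p,
                     "n_perm": n_perm, "seed": seed})
    df = pd.DataFrame(rows)
    df["rank_r"] = df["pearson_r"].rank(ascending=False, na_option="bottom")
    df["rank_z"] = df["perm_z"].rank(ascending=False, na_option="bottom")
    df["best_rank"] = df[["rank_r", "rank_z"]].min(axis=1)
    df["passes_both"] = (df["pearson_r"] > r_threshold) & (df["perm_z"] > z_threshold)
    df = df.sort_values(["best_rank", "rank_z", "target"]).reset_index(drop=True)
    return df
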