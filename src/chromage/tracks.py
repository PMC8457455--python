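"""Binned signal tracks, z-scoring, metaplots and boundary contrasts.

A :class:`BinnedTrack` holds one fixed-bin numeric array per chromosome
with a validity mask. The standard processing chain for a ChIP sample is
coverage -> log2(mark/control) -> genome-wide z-score; metaplots and
boundary contrasts are computed on the z-scored track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import DataError, GenomeLayout, RegionSet


@dataclass
class BinnedTrack:
    """Fixed-bin per-chromosome track with a missing-value mask.

    ``values[c]`` has ``ceil(length(c) / bin_size)`` entries; ``mask[c]``
    is True where the bin is valid. ``kind`` is one of ``coverage``,
    ``log2ratio`` or ``zscore``.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default=None)  # type: ignore[assignment]
    kind: str = "coverage"

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = {c: np.ones(len(v), dtype=bool) for c, v in self.values.items()}
        for c, v in self.values.items():
            expect = self.n_bins(c)
            if len(v) != expect or len(self.mask[c]) != expect:
                raise DataError(f"track array length mismatch on {c}: {len(v)} != {expect}")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.layout.length(chrom) / self.bin_size)

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int, kind: str = "coverage") -> "BinnedTrack":
        values = {c: np.zeros(math.ceil(layout.length(c) / bin_size)) for c in layout.chrom_names}
        return cls(layout, bin_size, values, None, kind)

    def flat(self, valid_only: bool = True) -> np.ndarray:
        parts = []
        for c in self.layout.chrom_names:
            if c not in self.values:
                continue
            v = self.values[c]
            parts.append(v[self.mask[c]] if valid_only else v)
        return np.concatenate(parts) if parts else np.array([])

    def total(self) -> float:
        return float(self.flat().sum())

    def value_at(self, chrom: str, pos: int) -> tuple[float, bool]:
        """(value, valid) of the bin containing pos."""
        b = pos // self.bin_size
        return float(self.values[chrom][b]), bool(self.mask[chrom][b])

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean over unmasked bins overlapping [start, end); NaN if none.

        Partial bins at the edges are included with full weight.
        """
        b0 = start // self.bin_size
        b1 = math.ceil(end / self.bin_size)
        v = self.values[chrom][b0:b1]
        m = self.mask[chrom][b0:b1]
        if not m.any():
            return float("nan")
        return float(v[m].mean())


def bin_coverage(
    placements: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = 20,
    extend: int = 200,
) -> tuple[BinnedTrack, int]:
    """Occupancy coverage track from read intervals.

    Each read is extended to ``extend`` bp from its 5' end (the start for
    +/unstranded reads, the end for - reads), clipped at chromosome ends,
    and contributes 1 to every bin it overlaps. Returns the track and the
    number of reads that had to be clipped.
    """
    track = BinnedTrack.zeros(layout, bin_size, kind="coverage")
    clipped = 0
    if placements.empty:
        return track, clipped
    strand = placements["strand"] if "strand" in placements.columns else pd.Series("." , index=placements.index)
    for chrom, sub in placements.groupby("chrom", sort=False):
        if chrom not in layout.chrom_lengths:
            raise DataError(f"read chromosome {chrom} not in layout")
        length = layout.length(chrom)
        st = sub["start"].to_numpy(np.int64)
        en = sub["end"].to_numpy(np.int64)
        sd = strand.loc[sub.index].to_numpy()
        neg = sd == "-"
        ext_start = np.where(neg, en - extend, st)
        ext_end = np.where(neg, en, st + extend)
        clipped += int(((ext_start < 0) | (ext_end > length)).sum())
        ext_start = np.clip(ext_start, 0, length)
        ext_end = np.clip(ext_end, 0, length)
        b0 = ext_start // bin_size
        b1 = (ext_end - 1) // bin_size + 1  # exclusive bin index
        arr = track.values[chrom]
        # difference-array accumulation of [b0, b1) increments
        diff = np.zeros(len(arr) + 1)
        np.add.at(diff, b0, 1.0)
        np.add.at(diff, b1, -1.0)
        arr += np.cumsum(diff[:-1])
    return track, clipped


def log2_ratio_track(
    treat: BinnedTrack,
    control: BinnedTrack,
    smooth: int = 60,
    pseudocount: float = 0.5,
    scale: bool = True,
) -> BinnedTrack:
    """log2(treatment/control) track with read-count scaling and smoothing.

    Both samples are scaled to equal total read count (geometric middle of
    the two totals) unless ``scale`` is False, a pseudocount is added to
    each bin, the ratio is logged, and a centered boxcar over
    ``ceil(smooth / bin_size)`` bins (edge-truncated) is applied. Bins
    where both samples are zero are masked.
    """
    if treat.bin_size != control.bin_size:
        raise DataError(f"bin size mismatch: {treat.bin_size} != {control.bin_size}")
    if treat.layout.chrom_lengths != control.layout.chrom_lengths:
        raise DataError("layout mismatch between treatment and control")
    if scale:
        tot_t, tot_c = treat.total(), control.total()
        if tot_t <= 0 or tot_c <= 0:
            raise DataError("cannot scale: a track has zero total")
        target = math.sqrt(tot_t * tot_c)
        sf_t, sf_c = target / tot_t, target / tot_c
    else:
        sf_t = sf_c = 1.0
    width = max(1, math.ceil(smooth / treat.bin_size))
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for c in treat.layout.chrom_names:
        t = treat.values[c]
        u = control.values[c]
        raw = np.log2((t * sf_t + pseudocount) / (u * sf_c + pseudocount))
        m = treat.mask[c] & control.mask[c] & ~((t == 0) & (u == 0))
        values[c] = _boxcar(raw, width, m)
        mask[c] = m
    return BinnedTrack(treat.layout, treat.bin_size, values, mask, kind="log2ratio")


def _boxcar(x: np.ndarray, width: int, mask: np.ndarray) -> np.ndarray:
    """Centered moving average over valid bins, edge-truncated."""
    if width <= 1:
        return x.copy()
    half = width // 2
    xv = np.where(mask, x, 0.0)
    kernel = np.ones(width)
    num = np.convolve(xv, kernel, mode="full")
    den = np.convolve(mask.astype(float), kernel, mode="full")
    # center the window: output bin i averages bins [i-half, i-half+width)
    lo = half if width % 2 == 1 else half  # same alignment either parity
    num = num[width - 1 - lo : width - 1 - lo + len(x)]
    den = den[width - 1 - lo : width - 1 - lo + len(x)]
    out = np.where(den > 0, num / np.maximum(den, 1e-300), x)
    return out


def zscore_track(track: BinnedTrack) -> BinnedTrack:
    """Genome-wide z-score of a log2-ratio track (population SD)."""
    if track.kind not in ("log2ratio", "zscore"):
        raise DataError(f"zscore_track expects a log2ratio track, got {track.kind}")
    vals = track.flat(valid_only=True)
    if len(vals) == 0:
        raise DataError("no valid bins to z-score")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0:
        raise DataError("constant track: SD is zero")
    values = {c: (v - mu) / sd for c, v in track.values.items()}
    mask = {c: m.copy() for c, m in track.mask.items()}
    return BinnedTrack(track.layout, track.bin_size, values, mask, kind="zscore")


def windowed_read_counts(
    placements: pd.DataFrame,
    layout: GenomeLayout,
    window: int = 15_000,
) -> np.ndarray:
    """Read counts in non-overlapping tiling windows (by read 5' end).

    Windows tile each chromosome with step = window; the last, possibly
    partial, window is kept. The result concatenates chromosomes in
    layout order.
    """
    if window <= 0:
        raise DataError("window must be positive")
    parts = []
    for chrom in layout.chrom_names:
        n_win = math.ceil(layout.length(chrom) / window)
        counts = np.zeros(n_win)
        if not placements.empty:
            sub = placements[placements["chrom"] == chrom]
            if len(sub):
                strand = sub["strand"].to_numpy() if "strand" in sub.columns else np.full(len(sub), ".")
                five = np.where(strand == "-", sub["end"].to_numpy(np.int64) - 1,
                                sub["start"].to_numpy(np.int64))
                idx = np.clip(five // window, 0, n_win - 1)
                np.add.at(counts, idx, 1.0)
        parts.append(counts)
    return np.concatenate(parts)


def track_to_windows(track: BinnedTrack, window: int) -> np.ndarray:
    """Sum a coverage track's bins into tiling windows of ``window`` bp."""
    parts = []
    for chrom in track.layout.chrom_names:
        v = track.values[chrom]
        per = window // track.bin_size
        n_win = math.ceil(len(v) / per)
        out = np.zeros(n_win)
        idx = np.arange(len(v)) // per
        np.add.at(out, idx, v)
        parts.append(out)
    return np.concatenate(parts)


def replicate_correlation(vectors: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson matrix for equal-length count vectors.

    Returns (matrix, defined) where ``defined[i, j]`` is False for pairs
    involving a zero-variance vector (their correlation entry is NaN).
    """
    n = len(vectors)
    lengths = {len(v) for v in vectors}
    if len(lengths) > 1:
        raise DataError(f"vectors have differing lengths: {sorted(lengths)}")
    mat = np.eye(n)
    defined = np.ones((n, n), dtype=bool)
    sds = [float(np.std(v)) for v in vectors]
    for i in range(n):
        for j in range(i + 1, n):
            if sds[i] == 0 or sds[j] == 0:
                mat[i, j] = mat[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
            else:
                r = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
                mat[i, j] = mat[j, i] = r
    for i in range(n):
        if sds[i] == 0:
            defined[i, i] = False
    return mat, defined


@dataclass
class MetaMatrix:
    """Region x position matrix for metaplots.

    Columns are: ``flank_bins`` upstream flank columns at native bin
    resolution, ``body_bins`` scaled-body columns, ``flank_bins``
    downstream columns.
    """

    values: np.ndarray          # (n_regions, n_cols)
    mask: np.ndarray            # same shape, True = valid
    flank_bins: int
    body_bins: int
    region_names: list[str]

    @property
    def n_cols(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def compute_matrix(
    track: BinnedTrack,
    regions: RegionSet,
    flank: int = 2000,
    body_bins: int = 100,
) -> tuple[MetaMatrix, int]:
    """Scaled-regions metaplot matrix with flanks at native resolution.

    Flanks are sampled at the track's bin size (``flank // bin_size``
    columns each side); region bodies are linearly rescaled to
    ``body_bins`` columns by sampling the track at body-fraction
    midpoints. Flank positions beyond chromosome ends are masked; regions
    shorter than one track bin are fully masked and counted as warnings.
    Returns (matrix, n_short_regions).
    """
    if len(regions) == 0:
        raise DataError("compute_matrix requires a non-empty region set")
    bs = track.bin_size
    fb = flank // bs
    n_cols = 2 * fb + body_bins
    n = len(regions)
    values = np.zeros((n, n_cols))
    mask = np.zeros((n, n_cols), dtype=bool)
    names = []
    short = 0
    for i, row in enumerate(regions.df.itertuples(index=False)):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        names.append(row.name if not pd.isna(row.name) else f"{chrom}:{start}-{end}")
        length = track.layout.length(chrom)
        if end - start < bs:
            short += 1
            continue
        tv = track.values[chrom]
        tm = track.mask[chrom]
        # upstream flank: fb native bins ending at region start
        pos_up = start - flank + (np.arange(fb) + 0.5) * bs
        pos_body = start + (np.arange(body_bins) + 0.5) / body_bins * (end - start)
        pos_dn = end + (np.arange(fb) + 0.5) * bs
        pos = np.concatenate([pos_up, pos_body, pos_dn])
        ok = (pos >= 0) & (pos < length)
        idx = np.clip(pos.astype(np.int64) // bs, 0, len(tv) - 1)
        values[i] = np.where(ok, tv[idx], 0.0)
        mask[i] = ok & tm[idx]
    return MetaMatrix(values, mask, fb, body_bins, names), short


def summarize_matrix(m: MetaMatrix) -> pd.DataFrame:
    """Per-column mean and 95% CI over unmasked cells.

    CI half-width is 1.96 * sd / sqrt(n) with the sample SD (ddof=1).
    Columns with < 2 valid cells carry NaN and defined=False.
    """
    if m.values.shape[0] < 2:
        raise DataError("summarize_matrix requires >= 2 rows")
    n_cols = m.values.shape[1]
    mean = np.full(n_cols, np.nan)
    ci = np.full(n_cols, np.nan)
    n_valid = m.mask.sum(axis=0)
    defined = n_valid >= 2
    for j in np.where(n_valid > 0)[0]:
        col = m.values[m.mask[:, j], j]
        mean[j] = col.mean()
        if len(col) >= 2:
            ci[j] = 1.96 * col.std(ddof=1) / math.sqrt(len(col))
    return pd.DataFrame({
        "column": np.arange(n_cols),
        "mean": mean,
        "ci95_halfwidth": ci,
        "n": n_valid,
        "defined": defined,
    })


def boundary_contrast(
    track: BinnedTrack,
    regions: RegionSet,
    w: int = 1000,
    mark: str = "active",
) -> tuple[pd.DataFrame, int]:
    """Signal contrast across each region edge.

    For each edge, computes the mean track value over the ``w`` bp just
    inside and just outside the region. For ``mark="active"`` the
    contrast is outside - inside (a sharp drop of an active mark at a
    repressive-domain boundary is positive); for ``mark="repressive"`` it
    is inside - outside. Edges whose outside window leaves the chromosome
    are skipped and counted. Returns (table, n_skipped).
    """
    if w < track.bin_size:
        raise DataError("w must be at least one bin")
    if mark not in ("active", "repressive"):
        raise DataError(f"mark must be 'active' or 'repressive', got {mark!r}")
    sign = 1.0 if mark == "active" else -1.0
    rows = []
    skipped = 0
    for row in regions.df.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        length = track.layout.length(chrom)
        for side, edge in (("left", start), ("right", end)):
            if side == "left":
                in_lo, in_hi = edge, min(edge + w, end)
                out_lo, out_hi = edge - w, edge
            else:
                in_lo, in_hi = max(edge - w, start), edge
                out_lo, out_hi = edge, edge + w
            if out_lo < 0 or out_hi > length:
                skipped += 1
                continue
            inside = track.region_mean(chrom, in_lo, in_hi)
            outside = track.region_mean(chrom, out_lo, out_hi)
            contrast = sign * (outside - inside)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": row.name, "side": side,
                         "inside_mean": inside, "outside_mean": outside,
                         "contrast": contrast})
    cols = ["chrom", "start", "end", "name", "side", "inside_mean", "outside_mean", "contrast"]
    return pd.DataFrame(rows, columns=cols), skipped


# ---- bedGraph I/O ------------------------------------------------------


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a 4-column bedGraph; masked bins are omitted, runs collapsed."""
    with open(path, "w") as fh:
        for chrom in track.layout.chrom_names:
            if chrom not in track.values:
                continue
            v = track.values[chrom]
            m = track.mask[chrom]
            length = track.layout.length(chrom)
            run_start = None
            run_val = None
            for b in range(len(v) + 1):
                cur = (v[b], True) if b < len(v) and m[b] else (None, False)
                if run_start is not None and (not cur[1] or cur[0] != run_val):
                    s = run_start * track.bin_size
                    e = min(b * track.bin_size, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{run_val:.6g}\n")
                    run_start = None
                if cur[1] and run_start is None:
                    run_start, run_val = b, cur[0]


def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_size: int, kind: str = "coverage") -> BinnedTrack:
    """Read a bedGraph whose intervals align to ``bin_size`` bins."""
    values = {c: np.zeros(math.ceil(layout.length(c) / bin_size)) for c in layout.chrom_names}
    mask = {c: np.zeros(math.ceil(layout.length(c) / bin_size), dtype=bool) for c in layout.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in values:
                raise DataError(f"{path}:{lineno}: chromosome {chrom} not in layout")
            b0 = s // bin_size
            b1 = math.ceil(e / bin_size)
            values[chrom][b0:b1] = val
            mask[chrom][b0:b1] = True
    return BinnedTrack(layout, bin_size, values, mask, kind=kind)
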