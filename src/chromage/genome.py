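"""Genome model and interval arithmetic.

Coordinates are 0-based, half-open everywhere: an interval [start, end)
covers ``end - start`` bp. BED input/output follows the same convention,
so file coordinates round-trip unchanged. Strand is carried on intervals
but ignored by all overlap math (the peak analyses are strandless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Malformed or inconsistent genomic input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeLayout:
    """Chromosome names/lengths plus labelled arm/center compartments.

    Compartments are half-open intervals per chromosome with a text label
    (``arm``, ``center``, or anything else such as ``X``). They may not
    overlap and must lie within the chromosome.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        compartments: Mapping[str, Sequence[tuple[int, int, str]]] | None = None,
    ) -> None:
        self.chrom_names: list[str] = list(chrom_lengths)
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise DataError(f"chromosome {c} has non-positive length {length}")
        self.compartments: dict[str, list[tuple[int, int, str]]] = {}
        for c, comps in (compartments or {}).items():
            if c not in self.chrom_lengths:
                raise DataError(f"compartment chromosome {c} not in layout")
            comps = sorted(comps)
            prev_end = 0
            for s, e, _lab in comps:
                if not (0 <= s < e <= self.chrom_lengths[c]):
                    raise DataError(f"compartment [{s},{e}) outside {c}")
                if s < prev_end:
                    raise DataError(f"overlapping compartments on {c}")
                prev_end = e
            self.compartments[c] = list(comps)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise DataError(f"chromosome {chrom} not in layout") from None

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def compartment_at(self, chrom: str, pos: int) -> str:
        """Label of the compartment whose half-open span contains pos."""
        for s, e, lab in self.compartments.get(chrom, []):
            if s <= pos < e:
                return lab
        return "unassigned"

    # ---- file I/O -------------------------------------------------

    @classmethod
    def from_files(cls, chrom_sizes: str | Path, compartments_bed: str | Path | None = None) -> "GenomeLayout":
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(chrom_sizes).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{chrom_sizes}:{i}: expected 'chrom<TAB>length'")
            lengths[parts[0]] = int(parts[1])
        comps: dict[str, list[tuple[int, int, str]]] = {}
        if compartments_bed is not None:
            regions = read_bed(compartments_bed)
            for iv in regions:
                comps.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.name or "unassigned"))
        return cls(lengths, comps)

    def to_files(self, chrom_sizes: str | Path, compartments_bed: str | Path | None = None) -> None:
        with open(chrom_sizes, "w") as fh:
            for c in self.chrom_names:
                fh.write(f"{c}\t{self.chrom_lengths[c]}\n")
        if compartments_bed is not None:
            with open(compartments_bed, "w") as fh:
                for c in self.chrom_names:
                    for s, e, lab in self.compartments.get(c, []):
                        fh.write(f"{c}\t{s}\t{e}\t{lab}\n")


_BED_COLUMNS = ["chrom", "start", "end", "name", "strand"]


class RegionSet:
    """A sorted, per-chromosome collection of half-open intervals.

    Backed by a pandas DataFrame with columns chrom/start/end/name/strand,
    kept sorted by (chrom, start, end). Chromosome order follows first
    appearance unless a layout is attached.
    """

    def __init__(self, df: pd.DataFrame | None = None, label: str = "") -> None:
        if df is None:
            df = pd.DataFrame(columns=_BED_COLUMNS)
        df = df.copy()
        for col, default in (("name", None), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_BED_COLUMNS]
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                row = df.iloc[i]
                raise DataError(
                    f"empty or inverted interval {row.chrom}:[{row.start},{row.end})"
                )
            if (df["start"] < 0).any():
                raise DataError("negative start coordinate")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.label = label

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], label: str = "") -> "RegionSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "name": iv.name, "strand": iv.strand}
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_BED_COLUMNS), label=label)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  None if pd.isna(row.name) else row.name,
                                  row.strand if row.strand in ("+", "-") else ".")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, sorted by start."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    def total_bp(self) -> int:
        """Covered bp, counting overlaps once (per-base footprint)."""
        total = 0
        for chrom in self.chroms:
            starts, ends = self.per_chrom(chrom)
            ms, me = _merge_sorted(starts, ends)
            total += int((me - ms).sum())
        return total

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(np.int64)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or book-ended sorted intervals on one chromosome."""
    if len(starts) == 0:
        return starts, ends
    # a new run begins where start exceeds the running max end so far
    max_end = np.maximum.accumulate(ends)
    new_run = np.ones(len(starts), dtype=bool)
    new_run[1:] = starts[1:] > max_end[:-1]
    run_id = np.cumsum(new_run) - 1
    out_starts = starts[new_run]
    out_ends = np.zeros(run_id[-1] + 1, dtype=np.int64)
    np.maximum.at(out_ends, run_id, ends)
    return out_starts, out_ends


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3/BED6 file (tab-separated, 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            rows.append({"chrom": parts[0], "start": start, "end": end, "name": name, "strand": strand})
    return RegionSet(pd.DataFrame(rows, columns=_BED_COLUMNS), label=str(path))


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write BED; BED6 when any name/strand is set, else BED3. Round-trips."""
    has_name = regions.df["name"].notna().any() if len(regions) else False
    has_strand = (regions.df["strand"].isin(["+", "-"])).any() if len(regions) else False
    with open(path, "w") as fh:
        for row in regions.df.itertuples(index=False):
            if has_name or has_strand:
                name = row.name if not pd.isna(row.name) else "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def union_regions(sets: Sequence[RegionSet], layout: GenomeLayout | None = None) -> RegionSet:
    """Minimal non-overlapping cover of all input sets.

    Book-ended intervals ([0,10) + [10,20)) merge. When a layout is given,
    chromosomes absent from it raise and output follows layout order.
    """
    frames = [s.df for s in sets if len(s)]
    if not frames:
        return RegionSet(label="union")
    df = pd.concat(frames, ignore_index=True)
    if layout is not None:
        unknown = set(df["chrom"]) - set(layout.chrom_names)
        if unknown:
            raise DataError(f"chromosomes not in layout: {sorted(unknown)}")
        chrom_order = [c for c in layout.chrom_names if c in set(df["chrom"])]
    else:
        chrom_order = sorted(set(df["chrom"]))
    rows = []
    for chrom in chrom_order:
        sub = df[df["chrom"] == chrom].sort_values(["start", "end"])
        ms, me = _merge_sorted(sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for s, e in zip(ms, me):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "name": None, "strand": "."})
    return RegionSet(pd.DataFrame(rows, columns=_BED_COLUMNS), label="union")


def overlap_bp(a: RegionSet, b: RegionSet) -> tuple[int, pd.DataFrame]:
    """Total overlapping bp between two sets, plus a per-a-interval table.

    The total uses the per-base footprints of both sets (so it is symmetric
    even when either set self-overlaps). The table gives, for each interval
    of ``a``, the bp of ``b``'s footprint covering it.
    """
    per_rows = []
    total = 0
    b_merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in b.chroms:
        b_merged[chrom] = _merge_sorted(*b.per_chrom(chrom))
    for row in a.df.itertuples(index=False):
        bs, be = b_merged.get(row.chrom, (np.array([], np.int64), np.array([], np.int64)))
        ov = 0
        if len(bs):
            lo = np.clip(bs, row.start, row.end)
            hi = np.clip(be, row.start, row.end)
            ov = int(np.maximum(hi - lo, 0).sum())
        per_rows.append({"chrom": row.chrom, "start": row.start, "end": row.end,
                         "name": row.name, "overlap_bp": ov})
    # symmetric total computed on footprints of both sides
    for chrom in a.chroms:
        as_, ae = _merge_sorted(*a.per_chrom(chrom))
        bs, be = b_merged.get(chrom, (np.array([], np.int64), np.array([], np.int64)))
        if not len(bs) or not len(as_):
            continue
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if hi > lo:
                total += int(hi - lo)
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
    table = pd.DataFrame(per_rows, columns=["chrom", "start", "end", "name", "overlap_bp"])
    return total, table


def assign_genes_to_regions(genes: RegionSet, peaks: RegionSet) -> pd.Series:
    """Map each named gene to the labels of peaks it overlaps (>= 1 bp).

    Genes overlapping no peak map to the string ``"non-peak"``; otherwise
    to a sorted list of peak names (or ``chrom:start-end`` for unnamed
    peaks). Duplicate gene names raise.
    """
    names = genes.df["name"]
    if names.isna().any():
        raise DataError("all genes must carry names")
    if names.duplicated().any():
        dups = sorted(names[names.duplicated()].unique())
        raise DataError(f"duplicate gene names: {dups}")
    out: dict[str, object] = {}
    peaks_by_chrom = {c: peaks.df[peaks.df["chrom"] == c] for c in peaks.chroms}
    for g in genes.df.itertuples(index=False):
        sub = peaks_by_chrom.get(g.chrom)
        labels: list[str] = []
        if sub is not None:
            hit = sub[(sub["start"] < g.end) & (sub["end"] > g.start)]
            for p in hit.itertuples(index=False):
                labels.append(p.name if not pd.isna(p.name) else f"{p.chrom}:{p.start}-{p.end}")
        out[g.name] = sorted(labels) if labels else "non-peak"
    return pd.Series(out, name="peaks")


def partition_by_compartment(regions: RegionSet, layout: GenomeLayout) -> list[str]:
    """Compartment label per region, decided by the region midpoint."""
    return [layout.compartment_at(row.chrom, (int(row.start) + int(row.end)) // 2)
            for row in regions.df.itertuples(index=False)]
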