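"""Shared fixtures: one synthetic dataset and one workflow run per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromage import PipelineConfig, SimulationConfig, write_fixture
from chromage.genome import GenomeLayout, RegionSet
from chromage.pipeline import FixtureData, load_fixture, run_chip_workflow, run_repeat_workflow


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    d = tmp_path_factory.mktemp("fixture") / "data"
    write_fixture(d, sim_config)
    return d


@pytest.fixture(scope="session")
def fx(fixture_dir) -> FixtureData:
    return load_fixture(fixture_dir)


@pytest.fixture(scope="session")
def workflow_out(tmp_path_factory, fixture_dir):
    """(chip_report, repeat_report, out_dir) from one shared end-to-end run."""
    out = tmp_path_factory.mktemp("workflow") / "out"
    cfg = PipelineConfig(fixture_dir=str(fixture_dir), out_dir=str(out))
    chip_report = run_chip_workflow(cfg)
    repeat_report = run_repeat_workflow(cfg)
    return chip_report, repeat_report, out


@pytest.fixture()
def toy_layout() -> GenomeLayout:
    return GenomeLayout(
        {"chrI": 100_000, "chrII": 50_000},
        {"chrI": [(0, 30_000, "arm"), (30_000, 70_000, "center"), (70_000, 100_000, "arm")]},
    )


def regions(*triples, names=None) -> RegionSet:
    """Build a RegionSet from (chrom, start, end) triples."""
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    if names is not None:
        df["name"] = names
    return RegionSet(df)


def coverage_mask(region_set: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean occupancy oracle for one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for row in region_set.df.itertuples(index=False):
        if row.chrom == chrom:
            mask[row.start:row.end] = True
    return mask


def merge_oracle(peaks: RegionSet, track, max_gap: int) -> RegionSet:
    """Exhaustive fixpoint oracle for the gap-merging rule.

    Repeatedly merges any adjacent pair whose gap is < max_gap and either
    book-ended or signal-positive, until no pair merges.
    """
    per_chrom = {}
    for chrom in peaks.chroms:
        starts, ends = peaks.per_chrom(chrom)
        items = [[int(s), int(e)] for s, e in zip(starts, ends)]
        changed = True
        while changed:
            changed = False
            for i in range(len(items) - 1):
                gap = items[i + 1][0] - items[i][1]
                if not (0 <= gap < max_gap):
                    continue
                if gap == 0:
                    ok = True
                else:
                    m = track.region_mean(chrom, items[i][1], items[i + 1][0])
                    ok = bool(np.isfinite(m) and m > 0)
                if ok:
                    items[i][1] = items[i + 1][1]
                    del items[i + 1]
                    changed = True
                    break
        per_chrom[chrom] = items
    rows = [{"chrom": c, "start": s, "end": e}
            for c, items in per_chrom.items() for s, e in items]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
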