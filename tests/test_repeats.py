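"""Multi-mapper counting policies, fractions and group enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromage.differential import DifferentialResult
from chromage.genome import DataError
from chromage.repeats import (RepeatAnnotation, categorize_placements,
                              count_repeat_reads, differential_repeats,
                              expressed_silent_partition, group_enrichment,
                              locus_mark_fc_table, repeat_fraction,
                              unmapped_fraction)


def annotation(loci, family="FAM1", klass="retrotransposon"):
    fams = [family] * len(loci) if isinstance(family, str) else family
    kls = [klass] * len(loci) if isinstance(klass, str) else klass
    return RepeatAnnotation(pd.DataFrame({
        "locus": loci, "chrom": "chrI",
        "start": np.arange(len(loci)) * 1000,
        "end": np.arange(len(loci)) * 1000 + 300,
        "strand": ".", "family": fams, "klass": kls,
    }))


def placements(rows):
    """rows: (sample, loci_string) pairs."""
    return pd.DataFrame({
        "read": [f"r{i}" for i in range(len(rows))],
        "sample": [s for s, _ in rows],
        "loci": [l for _, l in rows],
    })


def rna_meta(samples):
    meta = []
    for sid in samples:
        age, rep = sid.split("_")
        meta.append({"sample_id": sid, "age": age, "assay": "rna",
                     "replicate": int(rep.replace("rep", ""))})
    return pd.DataFrame(meta).set_index("sample_id")


class TestCategorize:
    def test_categories(self):
        p = placements([("s1", "L1"), ("s1", "L1,L2"), ("s1", "")])
        assert categorize_placements(p).tolist() == ["unique", "multi", "unplaced"]


class TestCountingPolicies:
    def test_policy_examples(self):
        ann = annotation(["L1", "L2"])
        meta = rna_meta(["young_rep1"])
        p = placements([("young_rep1", "L1,L2"), ("young_rep1", "L1"), ("young_rep1", "")])
        cm_all = count_repeat_reads(p, ann, meta, policy="all")
        cm_uni = count_repeat_reads(p, ann, meta, policy="unique")
        assert cm_all.counts["young_rep1"].tolist() == [2, 1]
        assert cm_uni.counts["young_rep1"].tolist() == [1, 0]

    def test_conservation_all_equals_matched_loci(self):
        rng = np.random.default_rng(6)
        loci = [f"L{i}" for i in range(10)]
        ann = annotation(loci)
        meta = rna_meta(["young_rep1", "old_rep1"])
        rows, expect = [], 0
        for i in range(300):
            sample = "young_rep1" if i % 2 else "old_rep1"
            k = int(rng.integers(0, 4))
            picked = list(rng.choice(loci, size=k, replace=False))
            expect += len(picked)
            rows.append((sample, ",".join(picked)))
        cm = count_repeat_reads(placements(rows), ann, meta, policy="all")
        assert int(cm.counts.to_numpy().sum()) == expect

    def test_all_dominates_unique(self):
        rng = np.random.default_rng(7)
        loci = [f"L{i}" for i in range(8)]
        ann = annotation(loci)
        meta = rna_meta(["young_rep1"])
        rows = [("young_rep1", ",".join(rng.choice(loci, size=int(rng.integers(0, 3)),
                                                   replace=False)))
                for _ in range(200)]
        p = placements(rows)
        cm_all = count_repeat_reads(p, ann, meta, policy="all")
        cm_uni = count_repeat_reads(p, ann, meta, policy="unique")
        assert (cm_all.counts.to_numpy() >= cm_uni.counts.to_numpy()).all()

    def test_unknown_locus_rejected(self):
        ann = annotation(["L1"])
        with pytest.raises(DataError, match="GHOST"):
            count_repeat_reads(placements([("young_rep1", "GHOST")]), ann,
                               rna_meta(["young_rep1"]))

    def test_unknown_sample_rejected(self):
        ann = annotation(["L1"])
        with pytest.raises(DataError, match="stranger"):
            count_repeat_reads(placements([("stranger", "L1")]), ann,
                               rna_meta(["young_rep1"]))

    def test_bad_policy(self):
        ann = annotation(["L1"])
        with pytest.raises(DataError):
            count_repeat_reads(placements([]), ann, rna_meta(["young_rep1"]),
                               policy="best")

    def test_total_mapped_becomes_library_size(self):
        ann = annotation(["L1"])
        meta = rna_meta(["young_rep1"])
        p = placements([("young_rep1", "L1")])
        tm = pd.Series({"young_rep1": 1_000_000.0})
        cm = count_repeat_reads(p, ann, meta, total_mapped=tm)
        assert cm.library_sizes["young_rep1"] == pytest.approx(1_000_000.0)


class TestFractions:
    def test_values_and_bounds(self):
        p = placements([("young_rep1", "L1"), ("young_rep1", "L1,L2"),
                        ("young_rep1", ""), ("old_rep1", "L1")])
        tm = pd.Series({"young_rep1": 10.0, "old_rep1": 4.0})
        ages = pd.Series({"young_rep1": "young", "old_rep1": "old"})
        frac, t, pv = repeat_fraction(p, tm, ages)
        assert frac["young_rep1"] == pytest.approx(0.2)  # multi-mapped read counts once
        assert frac["old_rep1"] == pytest.approx(0.25)
        assert math.isnan(t)  # fewer than 2 replicates per age

    def test_zero_total_rejected(self):
        p = placements([("young_rep1", "L1")])
        with pytest.raises(DataError, match="zero total"):
            repeat_fraction(p, pd.Series({"young_rep1": 0.0}),
                            pd.Series({"young_rep1": "young"}))

    def test_excess_reads_rejected(self):
        p = placements([("young_rep1", "L1"), ("young_rep1", "L2")])
        with pytest.raises(DataError, match="exceed"):
            repeat_fraction(p, pd.Series({"young_rep1": 1.0}),
                            pd.Series({"young_rep1": "young"}))

    def test_ttest_with_two_reps_each(self):
        rows = []
        for s, n in (("young_rep1", 2), ("young_rep2", 2), ("old_rep1", 6), ("old_rep2", 6)):
            rows += [(s, "L1")] * n
        tm = pd.Series({s: 100.0 for s in ("young_rep1", "young_rep2", "old_rep1", "old_rep2")})
        ages = pd.Series({"young_rep1": "young", "young_rep2": "young",
                          "old_rep1": "old", "old_rep2": "old"})
        frac, t, pv = repeat_fraction(placements(rows), tm, ages)
        assert ((frac >= 0) & (frac <= 1)).all()
        assert not math.isfinite(t)  # zero within-group variance -> undefined t
        rows[0] = ("young_rep1", "")  # break the tie
        frac, t, pv = repeat_fraction(placements(rows), tm, ages)
        assert t > 0 and 0 <= pv <= 1

    def test_unmapped_fraction(self):
        p = placements([("s1", ""), ("s1", "L1"), ("s1", "L1,L2"), ("s2", "L1")])
        uf = unmapped_fraction(p)
        assert uf["s1"] == pytest.approx(1 / 3)
        assert uf["s2"] == 0.0


class TestExpressedSilent:
    def test_boundary_inclusive(self):
        ann = annotation(["L1", "L2", "L3"])
        meta = rna_meta(["young_rep1"])
        rows = [("young_rep1", "L1")] * 5 + [("young_rep1", "L2")] * 4
        cm = count_repeat_reads(placements(rows), ann, meta)
        expressed, silent = expressed_silent_partition(cm, min_count=5)
        assert list(expressed) == ["L1"]
        assert sorted(silent) == ["L2", "L3"]


class TestDifferentialRepeats:
    def test_identical_counts_not_significant(self):
        rng = np.random.default_rng(19)
        loci = [f"L{i}" for i in range(20)]
        ann = annotation(loci)
        samples = ["young_rep1", "young_rep2", "old_rep1", "old_rep2"]
        meta = rna_meta(samples)
        base = rng.poisson(50, 20) + 10
        counts = pd.DataFrame({s: base for s in samples}, index=loci)
        features = ann.table.set_index("locus")[["chrom", "start", "end"]]
        from chromage.differential import CountMatrix
        cm = CountMatrix(counts, meta, features,
                         pd.Series(1e6, index=samples))
        res = differential_repeats(cm)
        assert (res.table["direction"] == "ns").all()
        assert (res.table["delta"].abs() < 1e-9).all()


class TestGroupEnrichment:
    def diff_with_up(self, loci, up):
        table = pd.DataFrame({
            "delta": [1.0 if l in up else 0.0 for l in loci],
            "s2": 0.1, "t_mod": 0.0, "p": 0.5, "q": 0.5,
            "direction": ["up" if l in up else "ns" for l in loci],
            "young_mean_z": np.nan, "asrr": False,
        }, index=pd.Index(loci, name="locus"))
        return DifferentialResult(table=table, d0=4.0, s0_sq=0.1, alpha=0.05)

    def test_hand_hypergeometric(self):
        # N=10, K=5, n=5, k=5 -> p = 1/C(10,5) = 1/252
        loci = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
        fams = ["FA"] * 5 + ["FB"] * 5
        ann = annotation(loci, family=fams)
        diff = self.diff_with_up(loci, {f"A{i}" for i in range(5)})
        out = group_enrichment(diff, ann, level="family", side="up")
        row = out[out["group"] == "FA"].iloc[0]
        assert row["p"] == pytest.approx(1 / 252)
        assert (row["k"], row["K"], row["n"], row["N"]) == (5, 5, 5, 10)

    def test_all_loci_differential_p_one(self):
        loci = [f"L{i}" for i in range(6)]
        fams = ["FA"] * 3 + ["FB"] * 3
        ann = annotation(loci, family=fams)
        diff = self.diff_with_up(loci, set(loci))
        out = group_enrichment(diff, ann, level="family", side="up")
        assert np.allclose(out["p"], 1.0)

    def test_low_power_flag(self):
        loci = [f"L{i}" for i in range(8)]
        fams = ["TINY"] * 2 + ["BIG"] * 6
        ann = annotation(loci, family=fams)
        diff = self.diff_with_up(loci, {"L0"})
        out = group_enrichment(diff, ann, level="family", side="up").set_index("group")
        assert bool(out.loc["TINY", "low_power"])
        assert not bool(out.loc["BIG", "low_power"])

    def test_matches_enumeration_oracle(self):
        # exhaustive check of hypergeom.sf against combinatorial enumeration
        loci = [f"L{i}" for i in range(8)]
        fams = ["FA"] * 3 + ["FB"] * 5
        ann = annotation(loci, family=fams)
        up = {"L0", "L1", "L4"}
        diff = self.diff_with_up(loci, up)
        out = group_enrichment(diff, ann, level="family", side="up").set_index("group")
        N, n = 8, 3
        for group, K in (("FA", 3), ("FB", 5)):
            k_obs = len(up & {l for l, f in zip(loci, fams) if f == group})
            count = 0
            for combo in itertools.combinations(range(N), n):
                k = sum(1 for i in combo if fams[i] == group)
                if k >= k_obs:
                    count += 1
            expect = count / math.comb(N, n)
            assert out.loc[group, "p"] == pytest.approx(expect, abs=1e-12)

    def test_class_level(self):
        loci = ["L1", "L2", "L3", "L4"]
        ann = annotation(loci, klass=["retrotransposon", "retrotransposon",
                                      "satellite", "satellite"])
        diff = self.diff_with_up(loci, {"L1", "L2"})
        out = group_enrichment(diff, ann, level="class", side="up")
        assert set(out["group"]) == {"retrotransposon", "satellite"}

    def test_bad_arguments(self):
        ann = annotation(["L1"])
        diff = self.diff_with_up(["L1"], set())
        with pytest.raises(DataError):
            group_enrichment(diff, ann, level="genus")
        with pytest.raises(DataError):
            group_enrichment(diff, ann, side="sideways")


class TestLocusMarkFc:
    def mark_result(self, deltas):
        idx = [f"m{i}" for i in range(len(deltas))]
        table = pd.DataFrame({
            "delta": deltas, "s2": 0.1, "t_mod": 0.0, "p": 0.5, "q": 0.5,
            "direction": "ns", "young_mean_z": np.nan, "asrr": False,
        }, index=idx)
        return DifferentialResult(table=table, d0=4.0, s0_sq=0.1, alpha=0.05)

    def test_perfect_correlation(self):
        loci = ["L1", "L2", "L3"]
        ann = annotation(loci)  # loci at [0,300), [1000,1300), [2000,2300)
        rna = TestGroupEnrichment().diff_with_up(loci, set())
        rna.table["delta"] = [0.5, 1.0, 2.0]
        marks = self.mark_result([0.5, 1.0, 2.0])
        mf = pd.DataFrame({"chrom": "chrI", "start": [0, 1000, 2000],
                           "end": [300, 1300, 2300]}, index=["m0", "m1", "m2"])
        table, meta = locus_mark_fc_table(rna, marks, mf, ann)
        assert meta["pearson_r"] == pytest.approx(1.0)
        assert meta["n_paired"] == 3

    def test_no_overlap_is_nan(self):
        loci = ["L1"]
        ann = annotation(loci)
        rna = TestGroupEnrichment().diff_with_up(loci, set())
        marks = self.mark_result([1.0])
        mf = pd.DataFrame({"chrom": "chrII", "start": [0], "end": [300]}, index=["m0"])
        table, meta = locus_mark_fc_table(rna, marks, mf, ann)
        assert math.isnan(table.loc["L1", "mark_delta"])
        assert math.isnan(meta["pearson_r"])

    def test_largest_effect_peak_wins(self):
        loci = ["L1"]
        ann = annotation(loci)
        rna = TestGroupEnrichment().diff_with_up(loci, set())
        marks = self.mark_result([0.3, -2.0])
        mf = pd.DataFrame({"chrom": "chrI", "start": [0, 100], "end": [200, 300]},
                          index=["m0", "m1"])
        table, _ = locus_mark_fc_table(rna, marks, mf, ann)
        assert table.loc["L1", "mark_delta"] == pytest.approx(-2.0)


class TestAnnotationValidation:
    def test_duplicate_locus(self):
        with pytest.raises(DataError, match="duplicate"):
            annotation(["L1", "L1"])

    def test_unknown_class(self):
        with pytest.raises(DataError, match="class"):
            annotation(["L1"], klass="plasmid")
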