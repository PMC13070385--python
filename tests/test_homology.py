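"""Homology splitting: PSL parsing, union overlap, the majority rule, bins."""

import numpy as np
import pytest

from seq2track.data import GenomicWindow
from seq2track.homology import (IntervalMapping, SplitPolicy, assign_all,
                                assign_region, homology_bins, overlap_bp,
                                parse_psl, write_psl, read_assignments,
                                write_assignments)


def psl_line(q_chrom="q1", q_start=0, q_end=300, t_chrom="t1", t_start=100,
             t_end=400, matches=300, strand="+"):
    span = q_end - q_start
    fields = [matches, 0, 0, 0, 0, 0, 0, 0, strand, q_chrom, 1000, q_start,
              q_end, t_chrom, 1000, t_start, t_end, 1, f"{span},",
              f"{q_start},", f"{t_start},"]
    return "\t".join(str(f) for f in fields)


class TestParsePsl:
    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text("\n".join(psl_line(q_start=i * 10, q_end=i * 10 + 100,
                                        matches=100) for i in range(3)) + "\n")
        mappings = parse_psl(p)
        assert len(mappings) == 3
        assert mappings[1].q_start == 10 and mappings[1].t_chrom == "t1"

    def test_headers_are_skipped(self, tmp_path):
        p = tmp_path / "h.psl"
        p.write_text("psLayout version 3\n\nmatch\tmis-match\n"
                     + "-" * 40 + "\n" + psl_line() + "\n")
        assert len(parse_psl(p)) == 1

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text("1\t2\t3\n")
        with pytest.raises(ValueError, match="21 PSL columns"):
            parse_psl(p)

    def test_negative_coordinate(self, tmp_path):
        p = tmp_path / "neg.psl"
        p.write_text(psl_line(t_start=-5, t_end=295) + "\n")
        with pytest.raises(ValueError, match="negative"):
            parse_psl(p)

    def test_write_read_roundtrip(self, tmp_path):
        m = IntervalMapping("qc", 5, 105, "tc", 50, 150, matches=95)
        write_psl([m], tmp_path / "rt.psl")
        back = parse_psl(tmp_path / "rt.psl")[0]
        assert (back.q_start, back.q_end, back.t_start, back.t_end,
                back.matches) == (5, 105, 50, 150, 95)


def brute_force_overlap(window, mappings, reference_set):
    """Per-base oracle: walk every base of the window through every mapping."""
    hit = np.zeros(window.length, dtype=bool)
    for m in mappings:
        if m.q_chrom != window.chrom:
            continue
        for q in range(max(m.q_start, window.start), min(m.q_end, window.end)):
            if m.strand == "+":
                t = m.t_start + (q - m.q_start)
            else:
                t = m.t_end - 1 - (q - m.q_start)
            for chrom, s, e in reference_set:
                if chrom == m.t_chrom and s <= t < e:
                    hit[q - window.start] = True
    return int(hit.sum())


class TestOverlap:
    def test_single_mapping(self):
        w = GenomicWindow("q1", 0, 1000)
        m = [IntervalMapping("q1", 0, 300, "t1", 500, 800, matches=300)]
        assert overlap_bp(w, m, [("t1", 0, 2000)]) == 300

    def test_union_semantics_not_double_counted(self):
        w = GenomicWindow("q1", 0, 1000)
        m = [IntervalMapping("q1", 100, 200, "t1", 0, 100, matches=100),
             IntervalMapping("q1", 100, 200, "t2", 0, 100, matches=100)]
        refs = [("t1", 0, 100), ("t2", 0, 100)]
        assert overlap_bp(w, m, refs) == 100

    def test_no_mappings(self):
        assert overlap_bp(GenomicWindow("q1", 0, 100), [], [("t1", 0, 10)]) == 0

    def test_matches_brute_force_on_random_instances(self):
        """Interval implementation equals the per-base scan on 200 random
        small instances, including minus-strand mappings."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            w = GenomicWindow("q1", int(rng.integers(0, 50)), int(rng.integers(60, 120)))
            mappings = []
            for _ in range(rng.integers(0, 5)):
                qs = int(rng.integers(0, 100))
                span = int(rng.integers(1, 40))
                ts = int(rng.integers(0, 100))
                strand = "+" if rng.random() < 0.7 else "-"
                mappings.append(IntervalMapping(
                    "q1", qs, qs + span,
                    rng.choice(["t1", "t2"]), ts, ts + span,
                    matches=span, strand=strand))
            refs = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(0, 120))
                refs.append((str(rng.choice(["t1", "t2"])), s, s + int(rng.integers(1, 50))))
            assert overlap_bp(w, mappings, refs) == brute_force_overlap(w, mappings, refs)


class TestAssign:
    W = GenomicWindow("q1", 0, 1000)

    def mappings(self, train_bp, val_bp):
        ms = []
        if train_bp:
            ms.append(IntervalMapping("q1", 0, train_bp, "t1", 0, train_bp,
                                      matches=train_bp))
        if val_bp:
            ms.append(IntervalMapping("q1", 500, 500 + val_bp, "t1",
                                      5000, 5000 + val_bp, matches=val_bp))
        return ms

    TRAIN = [("t1", 0, 2000)]
    VAL = [("t1", 4000, 6000)]

    def test_majority_goes_to_train(self):
        a = assign_region(self.W, self.mappings(300, 100), self.TRAIN, self.VAL)
        assert a.label == "train"
        assert a.overlap_train == 300 and a.overlap_validation == 100

    def test_validation_majority(self):
        a = assign_region(self.W, self.mappings(0, 250), self.TRAIN, self.VAL)
        assert a.label == "validation"

    def test_nonzero_tie_goes_to_validation(self):
        a = assign_region(self.W, self.mappings(200, 200), self.TRAIN, self.VAL)
        assert a.label == "validation"

    def test_zero_overlap_is_policy_seeded_and_deterministic(self):
        policy = SplitPolicy(holdout_ratios=(0.8, 0.1, 0.1), seed=7)
        ws = [GenomicWindow("q1", i * 1000, (i + 1) * 1000) for i in range(40)]
        l1 = [assign_region(w, [], self.TRAIN, self.VAL, policy).label for w in ws]
        l2 = [assign_region(w, [], self.TRAIN, self.VAL, policy).label for w in ws]
        assert l1 == l2
        # with a 0.8 train ratio, train must dominate and not be alone
        assert l1.count("train") > 20 and len(set(l1)) >= 2

    def test_labels_stable_under_mapping_permutation(self):
        ms = self.mappings(300, 100) + [
            IntervalMapping("q1", 700, 800, "t1", 1500, 1600, matches=100)]
        a1 = assign_region(self.W, ms, self.TRAIN, self.VAL)
        a2 = assign_region(self.W, ms[::-1], self.TRAIN, self.VAL)
        assert (a1.label, a1.overlap_train) == (a2.label, a2.overlap_train)

    def test_homology_proportion_bounds(self):
        ms = [IntervalMapping("q1", 0, 1000, "t1", 0, 1000, matches=1000),
              IntervalMapping("q1", 0, 1000, "t1", 500, 1500, matches=1000)]
        a = assign_region(self.W, ms, self.TRAIN, self.VAL)
        assert a.homology_proportion == 1.0

    def test_table_roundtrip(self, tmp_path):
        a = [assign_region(self.W, self.mappings(300, 100), self.TRAIN, self.VAL)]
        write_assignments(a, tmp_path / "a.tsv")
        back = read_assignments(tmp_path / "a.tsv")
        assert back == a


class TestHomologyBins:
    def make(self, props):
        from seq2track.homology import SplitAssignment
        return [SplitAssignment(f"w{i}", "test", 0, 0, p)
                for i, p in enumerate(props)]

    def test_binning_example(self):
        bins = homology_bins(self.make([0.0, 0.05, 0.5]), [0, 0.1, 1.0])
        sizes = [len(v) for v in bins.values()]
        assert sizes == [2, 1]

    def test_all_zero_proportions_in_first_bin(self):
        bins = homology_bins(self.make([0.0] * 5), [0, 0.5, 1.0])
        assert [len(v) for v in bins.values()] == [5, 0]

    def test_single_bin_contains_all(self):
        bins = homology_bins(self.make([0.1, 0.9, 1.0]), [0, 1.0])
        assert [len(v) for v in bins.values()] == [3]

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            homology_bins([], [0.5, 0.2, 1.0])
        with pytest.raises(ValueError):
            homology_bins([], [0.1, 1.0])


def test_world_assignments_partition_and_leakage(micro_world):
    """Every transfer window gets exactly one label, and held-out windows
    carry bounded homology to the reference training set."""
    sp = micro_world.species["transfer"]
    assert len(sp.splits) == len(sp.windows)
    assert set(sp.splits) <= {"train", "validation", "test"}
    props = [a.homology_proportion for a in micro_world.species_assignments
             if a.label != "train"]
    assert np.mean(props) <= 0.25
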