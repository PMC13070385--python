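"""Homology-aware train/validation/test assignment.

Nonreference regions are mapped onto a reference genome through PSL interval
mappings (as produced by pslMap/BLAT).  Each window is assigned to the split
whose reference interval set it overlaps most (through the mapping), so that
sequence homologous to reference training data cannot leak into held-out
splits.  Residual homology per window is quantified for leakage-binned
evaluation.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd

PSL_COLUMNS = 21


@dataclasses.dataclass
class IntervalMapping:
    """One aligned block pair: query (nonreference) -> target (reference)."""

    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    matches: int = 0
    strand: str = "+"

    def __post_init__(self):
        if self.q_start >= self.q_end or self.t_start >= self.t_end:
            raise ValueError("interval start must be < end on both sides")
        if min(self.q_start, self.t_start) < 0:
            raise ValueError("negative coordinate in interval mapping")
        if self.matches > min(self.q_end - self.q_start, self.t_end - self.t_start):
            raise ValueError("matched bases exceed the aligned span")


@dataclasses.dataclass
class SplitPolicy:
    """Tie and zero-overlap handling for :func:`assign_region`.

    Equal nonzero overlaps go to `tie_label` (validation by default, the
    conservative choice against leakage into train).  Windows with no mapped
    overlap at all are assigned by seeded draw with `holdout_ratios`.
    """

    tie_label: str = "validation"
    holdout_ratios: tuple = (0.8, 0.1, 0.1)  # train, validation, test
    seed: int = 0

    def zero_overlap_label(self, window_id: str) -> str:
        digest = hashlib.sha256(window_id.encode()).digest()
        key = int.from_bytes(digest[:4], "little")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, key]))
        return rng.choice(["train", "validation", "test"], p=self.holdout_ratios)


@dataclasses.dataclass
class SplitAssignment:
    window_id: str
    label: str
    overlap_train: int
    overlap_validation: int
    homology_proportion: float

    def __post_init__(self):
        if not 0.0 <= self.homology_proportion <= 1.0:
            raise ValueError("homology_proportion must lie in [0, 1]")


def parse_psl(path) -> list:
    """Read a PSL file (21 tab-separated columns) into interval mappings.

    Header lines ('psLayout', dashes, column names) are skipped; any other
    line with the wrong column count raises with its line number.
    """
    mappings = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            first = line.split("\t")[0].strip()
            if (not first or first.startswith(("psLayout", "match"))
                    or set(first) <= {"-"}):
                continue
            parts = line.split("\t")
            if len(parts) != PSL_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {PSL_COLUMNS} PSL columns, got {len(parts)}")
            try:
                m = IntervalMapping(
                    q_chrom=parts[9], q_start=int(parts[11]), q_end=int(parts[12]),
                    t_chrom=parts[13], t_start=int(parts[15]), t_end=int(parts[16]),
                    matches=int(parts[0]), strand=parts[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            mappings.append(m)
    return mappings


def write_psl(mappings, path):
    """Write single-block PSL lines (enough to round-trip parse_psl)."""
    with open(path, "w") as fh:
        for m in mappings:
            span = m.q_end - m.q_start
            fields = [m.matches, 0, 0, 0, 0, 0, 0, 0, m.strand,
                      m.q_chrom, 0, m.q_start, m.q_end,
                      m.t_chrom, 0, m.t_start, m.t_end,
                      1, f"{span},", f"{m.q_start},", f"{m.t_start},"]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def _merged_length(intervals) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cur_s, cur_e = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def overlap_bp(window, mappings, reference_set) -> int:
    """Bases of `window` whose mapped reference position falls in
    `reference_set`, each base counted once (union over mappings).

    `reference_set` is an iterable of (chrom, start, end) reference intervals.
    Mappings are assumed colinear within each block; minus-strand blocks map
    the query interval onto the reversed target interval.
    """
    ref_by_chrom = {}
    for chrom, s, e in reference_set:
        ref_by_chrom.setdefault(chrom, []).append((s, e))
    covered = []
    for m in mappings:
        if m.q_chrom != window.chrom:
            continue
        qs = max(m.q_start, window.start)
        qe = min(m.q_end, window.end)
        if qs >= qe:
            continue
        for rs, re_ in ref_by_chrom.get(m.t_chrom, ()):
            if m.strand == "+":
                ts = m.t_start + (qs - m.q_start)
                te = ts + (qe - qs)
                lo, hi = max(ts, rs), min(te, re_)
                if lo < hi:
                    covered.append((qs + (lo - ts), qs + (hi - ts)))
            else:
                # query base q maps to target t_end - 1 - (q - q_start)
                ts = m.t_end - (qe - m.q_start)
                te = m.t_end - (qs - m.q_start)
                lo, hi = max(ts, rs), min(te, re_)
                if lo < hi:
                    covered.append((m.q_start + (m.t_end - hi), m.q_start + (m.t_end - lo)))
    return _merged_length(covered)


def assign_region(window, mappings, train_set, validation_set,
                  policy: SplitPolicy | None = None) -> SplitAssignment:
    """Majority-overlap split rule: more mapped overlap with the reference
    training set than the validation set -> train, and vice versa."""
    policy = policy or SplitPolicy()
    ov_train = overlap_bp(window, mappings, train_set)
    ov_val = overlap_bp(window, mappings, validation_set)
    if ov_train > ov_val:
        label = "train"
    elif ov_val > ov_train:
        label = "validation"
    elif ov_train == 0:
        label = policy.zero_overlap_label(window.id)
    else:
        label = policy.tie_label
    prop = overlap_bp(window, mappings, train_set) / window.length
    return SplitAssignment(window.id, label, ov_train, ov_val, min(1.0, prop))


def assign_all(windows, mappings, train_set, validation_set, policy=None) -> list:
    return [assign_region(w, mappings, train_set, validation_set, policy)
            for w in windows]


def homology_bins(assignments, bin_edges) -> dict:
    """Group test-set assignments into homology-proportion bins.

    Edges must be strictly increasing and span [0, 1]; each test window falls
    in exactly one bin [edge_i, edge_{i+1}) (the last bin is closed above).
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0 or edges[-1] != 1:
        raise ValueError("bin edges must span [0, 1]")
    bins = {(edges[i], edges[i + 1]): [] for i in range(len(edges) - 1)}
    keys = list(bins)
    for a in assignments:
        if a.label != "test":
            continue
        i = np.searchsorted(edges, a.homology_proportion, side="right") - 1
        i = min(i, len(keys) - 1)
        bins[keys[i]].append(a.window_id)
    return bins


def assignments_to_table(assignments) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(a) for a in assignments])


def write_assignments(assignments, path):
    assignments_to_table(assignments).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [SplitAssignment(**row) for row in df.to_dict("records")]
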