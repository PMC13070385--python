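"""Windowed training examples from genomes and coverage tracks.

Converts FASTA sequence plus bedGraph coverage into fixed-length one-hot
windows paired with bin-summed count labels over the centered crop, the
geometry the model predicts.  Coordinates are 0-based half-open throughout
(BED/bedGraph convention); FASTA names are taken up to the first whitespace.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_ONE_HOT = np.vstack([np.eye(4, dtype=np.uint8), np.zeros((1, 4), dtype=np.uint8)])


@dataclasses.dataclass
class GenomicWindow:
    """A fixed-length reference interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    sequence: str = ""

    def __post_init__(self):
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval span")

    @property
    def length(self):
        return self.end - self.start

    @property
    def id(self):
        return f"{self.chrom}:{self.start}-{self.end}"


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T as unit vectors and N as all-zero; case-insensitive.

    Raises ValueError naming the offset of the first invalid character.
    """
    seq = sequence.upper()
    idx = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = np.full(idx.shape, -2, dtype=np.int64)
    for base, code in _BASE_INDEX.items():
        codes[idx == ord(base)] = code
    bad = np.nonzero(codes == -2)[0]
    if bad.size:
        off = int(bad[0])
        raise ValueError(f"invalid base {sequence[off]!r} at offset {off}")
    return _ONE_HOT[codes]


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    letters = np.array(list("ACGTN"))
    idx = np.where(matrix.sum(axis=1) == 0, 4, matrix.argmax(axis=1))
    return "".join(letters[idx])


def bin_signal(per_base_values: np.ndarray, bin_size: int, statistic: str = "sum") -> np.ndarray:
    """Aggregate per-base signal into fixed-width bins (sum by default)."""
    values = np.asarray(per_base_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("bin_signal expects a 1-D per-base vector")
    if values.size % bin_size:
        raise ValueError(
            f"length {values.size} is not a multiple of bin_size {bin_size}; "
            "pad or trim the vector to a whole number of bins")
    binned = values.reshape(-1, bin_size)
    if statistic == "sum":
        return binned.sum(axis=1)
    if statistic == "mean":
        return binned.mean(axis=1)
    raise ValueError(f"unknown bin statistic {statistic!r}")


def crop_center(values: np.ndarray, crop_length: int) -> np.ndarray:
    """Return the centered crop_length slice along the first axis."""
    values = np.asarray(values)
    n = values.shape[0]
    if crop_length > n:
        raise ValueError(f"crop_length {crop_length} exceeds input length {n}")
    if (n - crop_length) % 2:
        raise ValueError("input length minus crop_length must be even")
    off = (n - crop_length) // 2
    return values[off:off + crop_length]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """FASTA file -> {name: uppercase sequence}; names cut at whitespace."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_coverage(path, chrom_lengths: dict) -> dict:
    """bedGraph -> dense per-base vectors, one per chromosome.

    Intervals are 0-based half-open; positions not covered by any interval
    are zero.  Malformed lines raise with their line number.
    """
    cov = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}")
            chrom, s, e, v = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if s < 0 or e <= s:
                raise ValueError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            if chrom not in cov:
                continue
            cov[chrom][s:min(e, len(cov[chrom]))] += v
    return cov


def write_bedgraph(coverage: dict, path):
    """Dense per-base vectors -> run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            vec = np.asarray(coverage[chrom])
            if vec.size == 0:
                continue
            change = np.nonzero(np.diff(vec))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vec.size]])
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{vec[s]:g}\n")


# ---------------------------------------------------------------------------
# manifests and packed datasets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DatasetManifest:
    """Window records, track catalogue and provenance for one dataset."""

    records: list          # dicts: id, chrom, start, end, split
    track_names: list
    input_length: int
    crop_length: int
    bin_size: int
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        labels = {r["split"] for r in self.records}
        if not labels <= {"train", "validation", "test"}:
            raise ValueError(f"invalid split labels: {labels}")
        ids = [r["id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate window ids in manifest")

    def ids(self, split=None):
        return [r["id"] for r in self.records if split is None or r["split"] == split]

    def write(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path):
        return cls(**json.loads(Path(path).read_text()))


class Dataset:
    """In-memory example container: one-hot sequences and binned labels."""

    def __init__(self, manifest: DatasetManifest, X: np.ndarray, Y: np.ndarray):
        if X.shape[0] != len(manifest.records) or Y.shape[0] != X.shape[0]:
            raise ValueError("X/Y/manifest sizes disagree")
        self.manifest = manifest
        self.X = X  # (N, input_length, 4) uint8
        self.Y = Y  # (N, n_bins, n_tracks)

    @property
    def n_tracks(self):
        return self.Y.shape[2]

    @property
    def track_names(self):
        return self.manifest.track_names

    def indices(self, split):
        return np.array([i for i, r in enumerate(self.manifest.records)
                         if r["split"] == split], dtype=int)

    def subsample_windows(self, n_train, seed=0):
        """Seed-deterministically subsample training windows; validation and
        test windows are kept in full."""
        train = self.indices("train")
        keep = set(np.arange(len(self.manifest.records))) - set(train)
        if n_train < train.size:
            rng = np.random.default_rng(seed)
            keep |= set(rng.choice(train, size=n_train, replace=False).tolist())
        else:
            keep |= set(train.tolist())
        idx = np.array(sorted(keep), dtype=int)
        manifest = dataclasses.replace(
            self.manifest, records=[self.manifest.records[i] for i in idx],
            provenance=dict(self.manifest.provenance,
                            train_subsample=int(n_train), subsample_seed=seed))
        return Dataset(manifest, self.X[idx], self.Y[idx])

    def select_tracks(self, track_ids):
        """Subset tracks by index or name, preserving order of track_ids."""
        idx = [self.track_names.index(t) if isinstance(t, str) else int(t)
               for t in track_ids]
        manifest = dataclasses.replace(
            self.manifest, track_names=[self.track_names[i] for i in idx])
        return Dataset(manifest, self.X, self.Y[:, :, idx])

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest.write(directory / "manifest.json")
        np.savez_compressed(directory / "examples.npz", X=self.X, Y=self.Y)
        return directory

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        manifest = DatasetManifest.read(directory / "manifest.json")
        with np.load(directory / "examples.npz") as d:
            return cls(manifest, d["X"], d["Y"])


def make_examples(genome: dict, tracks: dict, windows, input_length: int,
                  crop_length: int, bin_size: int, splits=None,
                  subsample=None, seed=0, provenance=None) -> Dataset:
    """Assemble a Dataset from genome sequence and per-base coverage.

    `tracks` maps track name -> {chrom: per-base vector}; absent chromosomes
    count as zero coverage.  Windows that run off their chromosome are
    skipped with a logged warning.  Subsampling (of training windows' total)
    is deterministic in `seed`.
    """
    track_names = list(tracks)
    kept, skipped = [], 0
    windows = list(windows)
    splits = list(splits) if splits is not None else ["train"] * len(windows)
    for w, sp in zip(windows, splits):
        chrom = w.chrom if isinstance(w, GenomicWindow) else w[0]
        start = w.start if isinstance(w, GenomicWindow) else w[1]
        end = w.end if isinstance(w, GenomicWindow) else w[2]
        if end - start != input_length:
            raise ValueError(f"window {chrom}:{start}-{end} is not input_length long")
        if chrom not in genome or start < 0 or end > len(genome[chrom]):
            skipped += 1
            continue
        kept.append((chrom, start, end, sp))
    if skipped:
        logger.warning("skipped %d windows extending beyond their chromosome", skipped)
    if subsample is not None and subsample < len(kept):
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(len(kept), size=subsample, replace=False))
        kept = [kept[i] for i in sel]
    n_bins = crop_length // bin_size
    off = (input_length - crop_length) // 2
    X = np.zeros((len(kept), input_length, 4), dtype=np.uint8)
    Y = np.zeros((len(kept), n_bins, len(track_names)))
    records = []
    for i, (chrom, start, end, sp) in enumerate(kept):
        X[i] = one_hot_encode(genome[chrom][start:end])
        for j, t in enumerate(track_names):
            per_base = tracks[t].get(chrom)
            if per_base is None:
                continue
            segment = per_base[start + off:start + off + crop_length]
            Y[i, :, j] = bin_signal(segment, bin_size)
        records.append({"id": f"{chrom}:{start}-{end}", "chrom": chrom,
                        "start": int(start), "end": int(end), "split": sp})
    manifest = DatasetManifest(
        records=records, track_names=track_names, input_length=input_length,
        crop_length=crop_length, bin_size=bin_size,
        provenance=dict(provenance or {}, subsample=subsample, seed=seed,
                        skipped_windows=skipped))
    return Dataset(manifest, X, Y)
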