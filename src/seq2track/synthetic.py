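"""Desk-scale synthetic genomes, coverage tracks and cross-species transfer
worlds.

The generator emulates the structure of the real training corpora: a large
multi-track pretraining species and smaller fine-tuning species whose tracks
are driven partly by shared sequence features.  Random DNA carries planted
PWM motif occurrences; each track's per-bin Poisson rate is a softplus-linked
combination of a baseline and Gaussian-kernel contributions from nearby
occurrences of the motifs that task weights.  Exact duplicated segments
between species genomes provide the homology that the PSL-based splitter
consumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data import (Dataset, GenomicWindow, make_examples, write_bedgraph,
                   write_fasta)
from .homology import IntervalMapping, SplitPolicy, assign_all, write_psl


@dataclasses.dataclass
class MotifModel:
    """A set of position-weight matrices (rows are probability vectors)."""

    pwms: list            # each (L, 4)
    ids: list

    def __post_init__(self):
        for pwm in self.pwms:
            if not np.allclose(np.asarray(pwm).sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("every PWM row must sum to 1")


@dataclasses.dataclass
class TaskSpec:
    """One synthetic track: motif weights, baseline rate and kernel width."""

    task_id: str
    species: str
    motif_weights: dict      # motif id -> weight
    baseline_rate: float = 2.0
    bandwidth: int = 150     # bp

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if not all(np.isfinite(list(self.motif_weights.values()) or [0.0])):
            raise ValueError("motif weights must be finite")


@dataclasses.dataclass
class WorldConfig:
    """Geometry and generative settings for one synthetic world."""

    input_length: int = 4096
    crop_length: int = 2048
    bin_size: int = 128
    n_motifs: int = 12
    motif_length: int = 10
    sharing_fraction: float = 0.75
    n_pretrain_tasks: int = 40
    n_finetune_tasks: int = 3
    n_windows_reference: int = 360
    n_windows_species: int = 96
    gc_reference: float = 0.46
    gc_species: float = 0.50
    motif_rate_per_kb: float = 1.0    # occurrences per motif per kb
    baseline_rate: float = 1.0
    bandwidth: int = 150
    motifs_per_task: int = 3
    weight_scale: float = 5.0
    n_duplications: int = 12
    duplication_length: int = 1024
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sharing_fraction <= 1.0:
            raise ValueError("sharing fraction must lie in [0, 1]")
        if self.input_length % self.bin_size or self.crop_length % self.bin_size:
            raise ValueError("window geometry must be bin-aligned")
        if self.crop_length > self.input_length:
            raise ValueError("crop must not exceed input length")

    @classmethod
    def desk(cls, **kw):
        return cls(**kw)

    @classmethod
    def tiny(cls, **kw):
        defaults = dict(input_length=1024, crop_length=512, bin_size=64,
                        n_motifs=8, n_pretrain_tasks=12, n_finetune_tasks=3,
                        n_windows_reference=1536, n_windows_species=192,
                        motif_rate_per_kb=2.0,
                        duplication_length=512, n_duplications=8, bandwidth=96)
        defaults.update(kw)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def sample_motifs(n_motifs, length, seed) -> MotifModel:
    """Draw PWMs with Dirichlet(0.05) rows: ~1.6 bits per position, so a
    10-bp motif carries ~16 bits, comparable to real TF motifs and sharp
    enough to be detectable against random background."""
    if n_motifs < 1 or length < 4:
        raise ValueError("need n_motifs >= 1 and length >= 4")
    rng = np.random.default_rng(seed)
    pwms = [rng.dirichlet(np.full(4, 0.05), size=length) for _ in range(n_motifs)]
    return MotifModel(pwms=pwms, ids=[f"motif_{i}" for i in range(n_motifs)])


_BASES = np.array(list("ACGT"))


def sample_genome(length, gc, motif_model, motif_ids, rate_per_kb, seed):
    """Random background DNA with planted motif occurrences.

    Background bases are i.i.d. with the requested GC content; each motif in
    `motif_ids` is planted at Poisson(rate_per_kb * kb) positions sampled
    uniformly, instances drawn column-wise from its PWM.  Returns (sequence,
    occurrences) where occurrences is a list of (position, motif_id).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p)
    occurrences = []
    for mid in motif_ids:
        pwm = motif_model.pwms[motif_model.ids.index(mid)]
        L = pwm.shape[0]
        n_occ = rng.poisson(rate_per_kb * length / 1000.0)
        positions = np.sort(rng.integers(0, max(1, length - L), size=n_occ))
        for pos in positions:
            for j in range(L):
                seq[pos + j] = rng.choice(4, p=pwm[j])
            occurrences.append((int(pos), mid))
    occurrences.sort()
    return "".join(_BASES[seq]), occurrences


def task_rates(occurrences, task: TaskSpec, n_bins, bin_size, offset=0) -> np.ndarray:
    """Per-bin Poisson rate lambda for one task over [offset, offset+n_bins*bin).

    lambda(bin) = softplus(log(baseline) + sum_occ w(motif) * K(d, bandwidth))
    with a Gaussian kernel K in the distance d between occurrence and bin
    center.  Strictly positive by construction.
    """
    centers = offset + (np.arange(n_bins) + 0.5) * bin_size
    z = np.full(n_bins, np.log(task.baseline_rate))
    sigma = float(task.bandwidth)
    for pos, mid in occurrences:
        w = task.motif_weights.get(mid, 0.0)
        if w == 0.0:
            continue
        d = centers - pos
        near = np.abs(d) < 4 * sigma
        z[near] += w * np.exp(-0.5 * (d[near] / sigma) ** 2)
    return np.logaddexp(0.0, z)


def sample_counts(lam, seed) -> np.ndarray:
    """Independent Poisson draws at rates lam, deterministic in seed."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rates must be strictly positive")
    return np.random.default_rng(seed).poisson(lam)


def _sample_task(rng, task_id, species, motif_ids, cfg: WorldConfig) -> TaskSpec:
    k = min(cfg.motifs_per_task, len(motif_ids))
    chosen = rng.choice(motif_ids, size=k, replace=False)
    weights = {m: float(np.abs(rng.normal(cfg.weight_scale, cfg.weight_scale / 3)))
               for m in chosen}
    return TaskSpec(task_id=task_id, species=species, motif_weights=weights,
                    baseline_rate=cfg.baseline_rate, bandwidth=cfg.bandwidth)


# ---------------------------------------------------------------------------
# the world
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpeciesWorld:
    name: str
    genome: dict                 # chrom -> sequence
    occurrences: dict            # chrom -> list of (pos, motif_id)
    tasks: list                  # TaskSpec
    counts: dict                 # task_id -> {chrom: per-bin counts}
    windows: list                # GenomicWindow
    splits: list                 # per-window labels

    def coverage(self, bin_size):
        """Per-base read-depth vectors (count spread evenly over its bin)."""
        tracks = {}
        for task in self.tasks:
            per_chrom = {}
            for chrom, counts in self.counts[task.task_id].items():
                per_chrom[chrom] = np.repeat(counts / bin_size, bin_size)
            tracks[task.task_id] = per_chrom
        return tracks


class World:
    """A generated synthetic world: reference species + transfer species."""

    def __init__(self, config: WorldConfig, species: dict, motif_model: MotifModel,
                 mappings: list, reference_name: str):
        self.config = config
        self.species = species
        self.motif_model = motif_model
        self.mappings = mappings
        self.reference_name = reference_name

    def reference_intervals(self, split):
        ref = self.species[self.reference_name]
        return [(w.chrom, w.start, w.end)
                for w, s in zip(ref.windows, ref.splits) if s == split]

    def dataset(self, species_name, task_ids=None) -> Dataset:
        sp = self.species[species_name]
        cfg = self.config
        tasks = [t for t in sp.tasks
                 if task_ids is None or t.task_id in set(task_ids)]
        tracks = {}
        for task in tasks:
            tracks[task.task_id] = {
                chrom: np.repeat(sp.counts[task.task_id][chrom] / cfg.bin_size,
                                 cfg.bin_size)
                for chrom in sp.genome}
        return make_examples(
            sp.genome, tracks, sp.windows, cfg.input_length, cfg.crop_length,
            cfg.bin_size, splits=sp.splits,
            provenance={"species": species_name, "world_seed": cfg.seed})

    def write(self, directory):
        """Persist the world in standard formats (FASTA/bedGraph/BED/PSL)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, sp in self.species.items():
            d = directory / name
            d.mkdir(exist_ok=True)
            write_fasta(sp.genome, d / "genome.fa")
            for task in sp.tasks:
                cov = {c: np.repeat(sp.counts[task.task_id][c] / self.config.bin_size,
                                    self.config.bin_size) for c in sp.genome}
                write_bedgraph(cov, d / f"{task.task_id}.bedGraph")
            with open(d / "occurrences.bed", "w") as fh:
                for chrom, occ in sp.occurrences.items():
                    for pos, mid in occ:
                        fh.write(f"{chrom}\t{pos}\t{pos + self.config.motif_length}\t{mid}\n")
            manifest = {
                "species": name,
                "tasks": [dataclasses.asdict(t) for t in sp.tasks],
                "windows": [{"chrom": w.chrom, "start": w.start, "end": w.end,
                             "split": s} for w, s in zip(sp.windows, sp.splits)],
            }
            (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        write_psl(self.mappings, directory / "homology.psl")
        (directory / "world.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2))
        return directory


def _tile_windows(chrom, genome_length, cfg: WorldConfig):
    stride = cfg.crop_length  # crops tile the genome without overlap
    windows = []
    start = 0
    while start + cfg.input_length <= genome_length:
        windows.append(GenomicWindow(chrom, start, start + cfg.input_length))
        start += stride
    return windows


def _contiguous_splits(n, fractions=(0.7, 0.15, 0.15)):
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    return (["train"] * n_train + ["validation"] * n_val
            + ["test"] * (n - n_train - n_val))


def generate_world(config: WorldConfig) -> World:
    """Generate the full synthetic world deterministically from config.seed.

    The reference species carries the pretraining task corpus; one transfer
    species shares `sharing_fraction` of the motif vocabulary (with fresh
    task weights) plus species-specific motifs and a shifted GC content, so
    transfer from the reference is informative but not trivial.  Duplicated
    segments copied from the reference genome into the transfer genome are
    recorded as PSL mappings.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    s_motif, s_ref, s_sp, s_tasks, s_counts, s_dup = root.spawn(6)

    n_shared = int(round(cfg.sharing_fraction * cfg.n_motifs))
    n_own = cfg.n_motifs - n_shared
    total_motifs = cfg.n_motifs + n_own  # shared + reference-own + species-own
    motif_model = sample_motifs(total_motifs, cfg.motif_length,
                                np.random.default_rng(s_motif).integers(2 ** 31))
    shared_ids = motif_model.ids[:n_shared]
    ref_ids = shared_ids + motif_model.ids[n_shared:cfg.n_motifs]
    sp_ids = shared_ids + motif_model.ids[cfg.n_motifs:]

    def build_species(name, gc, motif_ids, n_tasks, n_windows, gseed, tseed, cseed):
        glen = n_windows * cfg.crop_length + (cfg.input_length - cfg.crop_length)
        seq, occ = sample_genome(glen, gc, motif_model, motif_ids,
                                 cfg.motif_rate_per_kb, gseed)
        chrom = f"{name}_chr1"
        task_rng = np.random.default_rng(tseed)
        tasks = [_sample_task(task_rng, f"{name}_task{i}", name, motif_ids, cfg)
                 for i in range(n_tasks)]
        return SpeciesWorld(name=name, genome={chrom: seq},
                            occurrences={chrom: occ}, tasks=tasks, counts={},
                            windows=[], splits=[]), chrom

    ref_rng = np.random.default_rng(s_ref)
    sp_rng = np.random.default_rng(s_sp)
    task_rng = np.random.default_rng(s_tasks)
    ref, ref_chrom = build_species(
        "reference", cfg.gc_reference, ref_ids, cfg.n_pretrain_tasks,
        cfg.n_windows_reference, ref_rng.integers(2 ** 31),
        task_rng.integers(2 ** 31), None)
    sp, sp_chrom = build_species(
        "transfer", cfg.gc_species, sp_ids, cfg.n_finetune_tasks,
        cfg.n_windows_species, sp_rng.integers(2 ** 31),
        task_rng.integers(2 ** 31), None)

    # exact duplicated segments reference -> transfer, recorded as PSL
    dup_rng = np.random.default_rng(s_dup)
    mappings = []
    sp_seq = list(sp.genome[sp_chrom])
    ref_seq = ref.genome[ref_chrom]
    L = cfg.duplication_length
    sp_occ = [o for o in sp.occurrences[sp_chrom]]
    pasted = []
    for _ in range(cfg.n_duplications):
        t0 = int(dup_rng.integers(0, len(ref_seq) - L))
        q0 = int(dup_rng.integers(0, len(sp_seq) - L))
        sp_seq[q0:q0 + L] = ref_seq[t0:t0 + L]
        pasted.append((q0, t0))
        mappings.append(IntervalMapping(
            q_chrom=sp_chrom, q_start=q0, q_end=q0 + L,
            t_chrom=ref_chrom, t_start=t0, t_end=t0 + L, matches=L))
    sp.genome[sp_chrom] = "".join(sp_seq)
    # keep labels consistent with the pasted sequence: drop occurrences the
    # paste overwrote, and carry over the reference occurrences it contains
    # (shared motifs keep driving signal in conserved sequence; reference-only
    # motifs are neutral for transfer tasks, which do not weight them)
    for q0, t0 in pasted:
        sp_occ = [(p, m) for p, m in sp_occ
                  if p + cfg.motif_length <= q0 or p >= q0 + L]
        sp_occ += [(q0 + (p - t0), m) for p, m in ref.occurrences[ref_chrom]
                   if t0 <= p and p + cfg.motif_length <= t0 + L]
    sp.occurrences[sp_chrom] = sorted(sp_occ)

    # windows and splits
    ref.windows = _tile_windows(ref_chrom, len(ref.genome[ref_chrom]), cfg)
    ref.splits = _contiguous_splits(len(ref.windows))
    sp.windows = _tile_windows(sp_chrom, len(sp.genome[sp_chrom]), cfg)
    world = World(cfg, {"reference": ref, "transfer": sp}, motif_model,
                  mappings, "reference")
    assignments = assign_all(
        sp.windows, mappings, world.reference_intervals("train"),
        world.reference_intervals("validation"),
        SplitPolicy(holdout_ratios=(0.6, 0.2, 0.2), seed=cfg.seed))
    sp.splits = [a.label for a in assignments]
    world.species_assignments = assignments

    # counts for every task on the bin grid of each genome
    count_rng = np.random.default_rng(s_counts)
    for species in (ref, sp):
        for task in species.tasks:
            per_chrom = {}
            for chrom, seq in species.genome.items():
                n_bins = len(seq) // cfg.bin_size
                lam = task_rates(species.occurrences[chrom], task,
                                 n_bins, cfg.bin_size)
                per_chrom[chrom] = sample_counts(
                    lam, int(count_rng.integers(2 ** 31)))
            species.counts[task.task_id] = per_chrom
    return world
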