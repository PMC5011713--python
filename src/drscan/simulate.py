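"""Seeded synthetic genomes with planted CRISPR arrays and truth tables.

The generator emulates a prokaryotic genome: i.i.d. background at a
configurable GC content, with CRISPR arrays planted at well-separated
positions.  DR lengths default to the empirical 23-55 bp band and spacers
to 20-60 bp; per-copy divergence introduces point mutations at an exact
count per copy.  Spacers are re-sampled until mutually dissimilar
(pairwise similar ratio <= 0.4), so a planted array always passes the
spacer false-positive filter and detection failures are attributable to
the detector, not the fixture.  Corruption operators reproduce the known
failure modes of CRISPR annotators: a truncated terminal DR, a strongly
degenerate internal DR (which splits naive annotations in two), a
below-minimum spacer, and a tandem microsatellite decoy that superficially
resembles an array but has no spacers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES
from .clustering import similarity_ratio
from .evaluation import GoldArray, write_gold_table
from .io import GenomeRecord, Interval, write_fasta

CORRUPTIONS = {"truncate_terminal_dr", "degenerate_internal_dr", "short_spacer", "tandem_decoy"}
_MARGIN = 500  # bp clearance around every planted block
_SHORT_SPACER_LEN = 7
_TRUNCATE_FRACTION = 0.6
_DEGENERATE_RATE = 0.3
_SPACER_MAX_MUTUAL_SIM = 0.4


@dataclass
class PlantSpec:
    genome_len: int = 100_000
    n_arrays: int = 1
    dr_len_range: tuple[int, int] = (23, 55)
    dr_copies_range: tuple[int, int] = (3, 30)
    spacer_len_range: tuple[int, int] = (20, 60)
    dr_divergence: float = 0.0
    corruptions: frozenset[str] = field(default_factory=frozenset)
    gc: float = 0.5
    seed: int = 0
    seq_id: str = "synthetic"

    def __post_init__(self) -> None:
        bad = set(self.corruptions) - CORRUPTIONS
        if bad:
            raise ValueError(f"unknown corruptions: {sorted(bad)}")
        if not 23 <= self.dr_len_range[0] <= self.dr_len_range[1] <= 55:
            raise ValueError("dr_len_range must lie within [23, 55]")
        if not 0 <= self.dr_divergence < 0.5:
            raise ValueError("dr_divergence must be in [0, 0.5)")


@dataclass
class TruthAnnotation:
    arrays: list[GoldArray]
    planted_sequences: list[tuple[str, str, list[str]]]
    decoy_intervals: list[Interval] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def _mutate_exact(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Mutate exactly round(rate*len) positions, each to a different base."""
    k = int(round(rate * len(seq)))
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in positions:
        old = "ACGT".index(out[p])
        out[p] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _sample_spacer(
    rng: np.random.Generator, length: int, gc: float, existing: list[str], max_tries: int = 100
) -> str:
    best, best_sim = None, None
    for _ in range(max_tries):
        cand = _random_seq(rng, length, gc)
        sim = max((similarity_ratio(cand, e) for e in existing), default=0.0)
        if sim <= _SPACER_MAX_MUTUAL_SIM:
            return cand
        if best_sim is None or sim < best_sim:
            best, best_sim = cand, sim
    return best  # pragma: no cover - essentially unreachable for random DNA


def generate_genome(spec: PlantSpec) -> tuple[GenomeRecord, TruthAnnotation]:
    """Build the genome and its truth annotation, fully reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    blocks: list[tuple[str, list[tuple[int, int]], str, list[str]]] = []
    # per array: (block_seq, DR (offset,end) pairs inside the block, master DR, spacers)
    for ai in range(spec.n_arrays):
        dr_len = int(rng.integers(spec.dr_len_range[0], spec.dr_len_range[1] + 1))
        n_copies = int(rng.integers(spec.dr_copies_range[0], spec.dr_copies_range[1] + 1))
        master = _random_seq(rng, dr_len, spec.gc)
        copies = [_mutate_exact(rng, master, spec.dr_divergence) for _ in range(n_copies)]
        spacers: list[str] = []
        for _ in range(n_copies - 1):
            slen = int(rng.integers(spec.spacer_len_range[0], spec.spacer_len_range[1] + 1))
            spacers.append(_sample_spacer(rng, slen, spec.gc, spacers))

        if "short_spacer" in spec.corruptions and ai == 0 and spacers:
            spacers[-1] = _random_seq(rng, _SHORT_SPACER_LEN, spec.gc)
        if "degenerate_internal_dr" in spec.corruptions and ai == 0 and n_copies >= 3:
            mid = n_copies // 2
            copies[mid] = _mutate_exact(rng, master, _DEGENERATE_RATE)
        if "truncate_terminal_dr" in spec.corruptions and ai == 0:
            keep = max(int(round(_TRUNCATE_FRACTION * dr_len)), 1)
            copies[-1] = copies[-1][:keep]  # outer (right) side truncated

        parts, dr_offsets = [], []
        pos = 0
        for i, c in enumerate(copies):
            dr_offsets.append((pos, pos + len(c)))
            parts.append(c)
            pos += len(c)
            if i < len(spacers):
                parts.append(spacers[i])
                pos += len(spacers[i])
        blocks.append(("".join(parts), dr_offsets, master, spacers))

    decoy_seq = ""
    if "tandem_decoy" in spec.corruptions:
        unit = _random_seq(rng, 35, spec.gc)
        decoy_seq = unit * 10

    block_seqs = [b[0] for b in blocks] + ([decoy_seq] if decoy_seq else [])
    total = sum(len(s) for s in block_seqs)
    slack = spec.genome_len - total - _MARGIN * (len(block_seqs) + 1)
    if slack < 0:
        raise ValueError("planted arrays plus margins do not fit in genome_len")
    n_gaps = len(block_seqs) + 1
    extra = rng.multinomial(slack, [1.0 / n_gaps] * n_gaps) if n_gaps else []

    genome_parts: list[str] = []
    positions: list[int] = []
    cursor = 0
    for i, bs in enumerate(block_seqs):
        gap = _MARGIN + int(extra[i])
        genome_parts.append(_random_seq(rng, gap, spec.gc))
        cursor += gap
        positions.append(cursor)
        genome_parts.append(bs)
        cursor += len(bs)
    genome_parts.append(_random_seq(rng, spec.genome_len - cursor, spec.gc))
    genome = GenomeRecord(spec.seq_id, "".join(genome_parts))
    assert genome.length == spec.genome_len

    golds, planted = [], []
    for ai, (bs, offsets, master, spacers) in enumerate(blocks):
        base = positions[ai]
        gid = f"G{ai + 1}"
        ivs = [Interval(spec.seq_id, base + s, base + e) for s, e in offsets]
        golds.append(GoldArray(gid, spec.seq_id, ivs))
        planted.append((gid, master, spacers))
    decoys = []
    if decoy_seq:
        d0 = positions[-1]
        decoys.append(Interval(spec.seq_id, d0, d0 + len(decoy_seq)))
    return genome, TruthAnnotation(golds, planted, decoys)


def apply_terminal_divergence(
    genome: GenomeRecord,
    truth: TruthAnnotation,
    gold_id: str,
    rate: float,
    seed: int = 0,
) -> GenomeRecord:
    """Regression-scenario helper: mutate the first and last DR copy of one
    planted array at an exact per-copy rate (terminal copies of real arrays
    are often degenerate and get missed by stringent mapping)."""
    rng = np.random.default_rng(seed)
    gold = next(g for g in truth.arrays if g.gold_id == gold_id)
    seq = genome.sequence
    for iv in (gold.dr_intervals[0], gold.dr_intervals[-1]):
        mutated = _mutate_exact(rng, seq[iv.start : iv.end], rate)
        seq = seq[: iv.start] + mutated + seq[iv.end :]
    return GenomeRecord(genome.seq_id, seq)


def write_fixture(
    spec: PlantSpec, out_dir: str | Path, name: str = "synthetic"
) -> tuple[Path, Path]:
    """Emit the genome as FASTA and the truth as a gold TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(spec)
    fasta = write_fasta([genome], out_dir / f"{name}.fasta")
    gold = write_gold_table(truth.arrays, out_dir / f"{name}.gold.tsv")
    return fasta, gold
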