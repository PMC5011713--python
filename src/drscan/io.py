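"""Genome input, coordinate conventions, and annotation output.

Internally every coordinate is 0-based half-open on the forward strand.
All emitted files (tab-delimited tables and GFF3) use 1-based inclusive
coordinates, the convention of the interchange formats themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import encode

if TYPE_CHECKING:  # pragma: no cover
    from .arrays import CRISPRArray

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass
class GenomeRecord:
    """One named nucleotide sequence; the search space of the pipeline."""

    seq_id: str
    sequence: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"non-normalized characters in {self.seq_id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """uint8 encoding (A=0..T=3, N=4), computed once and cached."""
        if self._codes is None:
            self._codes = encode(self.sequence)
        return self._codes


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def normalize_sequence(raw: str, seq_id: str = "?") -> str:
    """Uppercase and map IUPAC ambiguity codes (anything not ACGTN) to N."""
    seq = raw.upper()
    if set(seq) <= _VALID:
        return seq
    n_mapped = sum(1 for c in seq if c not in _VALID)
    logger.warning("%s: %d ambiguity characters mapped to N", seq_id, n_mapped)
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) genome FASTA into GenomeRecords, in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


def _sorted_arrays(arrays: Sequence["CRISPRArray"]) -> list["CRISPRArray"]:
    return sorted(arrays, key=lambda a: (a.seq_id, a.span.start))


ARRAY_COLUMNS = ["array_id", "seq_id", "start", "end", "n_DR", "n_spacer", "consensus_DR"]
DR_COLUMNS = ["array_id", "index", "seq_id", "start", "end", "sequence", "identity_to_consensus"]
SPACER_COLUMNS = ["array_id", "index", "seq_id", "start", "end", "sequence"]


def write_annotation_tables(
    arrays: Sequence["CRISPRArray"], out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write the three tab-delimited outputs (arrays, DR copies, spacers).

    Coordinates are 1-based inclusive; rows sorted by (seq_id, start) so the
    files are byte-stable for identical input.
    """
    out_prefix = Path(out_prefix)
    p_arr = out_prefix.with_name(out_prefix.name + ".arrays.tsv")
    p_dr = out_prefix.with_name(out_prefix.name + ".drs.tsv")
    p_sp = out_prefix.with_name(out_prefix.name + ".spacers.tsv")
    arrays = _sorted_arrays(arrays)
    with open(p_arr, "w") as fa, open(p_dr, "w") as fd, open(p_sp, "w") as fs:
        fa.write("\t".join(ARRAY_COLUMNS) + "\n")
        fd.write("\t".join(DR_COLUMNS) + "\n")
        fs.write("\t".join(SPACER_COLUMNS) + "\n")
        for arr in arrays:
            fa.write(
                f"{arr.array_id}\t{arr.seq_id}\t{arr.span.start + 1}\t{arr.span.end}\t"
                f"{arr.n_dr}\t{arr.n_spacer}\t{arr.consensus_dr}\n"
            )
            for i, (hit, seq, ident) in enumerate(
                zip(arr.dr_copies, arr.dr_sequences, arr.dr_identities), start=1
            ):
                loc = hit.location
                fd.write(
                    f"{arr.array_id}\t{i}\t{arr.seq_id}\t{loc.start + 1}\t{loc.end}\t"
                    f"{seq}\t{ident:.4f}\n"
                )
            for i, (sp, seq) in enumerate(zip(arr.spacers, arr.spacer_sequences), start=1):
                fs.write(
                    f"{arr.array_id}\t{i}\t{arr.seq_id}\t{sp.start + 1}\t{sp.end}\t{seq}\n"
                )
    return p_arr, p_dr, p_sp


def _gff_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(arrays: Sequence["CRISPRArray"], path: str | Path) -> Path:
    """Write arrays as GFF3: repeat_region parents with direct_repeat and
    binding_site (crispr_role=spacer) children."""
    path = Path(path)
    arrays = _sorted_arrays(arrays)
    lines = ["##gff-version 3"]
    for arr in arrays:
        sid = _gff_escape(arr.seq_id)
        aid = _gff_escape(arr.array_id)
        score = f"{arr.mean_identity:.3f}"
        lines.append(
            f"{sid}\tdrscan\trepeat_region\t{arr.span.start + 1}\t{arr.span.end}\t{score}\t"
            f"{arr.strand}\t.\tID={aid};n_dr={arr.n_dr};n_spacer={arr.n_spacer};"
            f"consensus_dr={arr.consensus_dr}"
        )
        for i, (hit, ident) in enumerate(zip(arr.dr_copies, arr.dr_identities), start=1):
            loc = hit.location
            lines.append(
                f"{sid}\tdrscan\tdirect_repeat\t{loc.start + 1}\t{loc.end}\t{ident:.3f}\t"
                f"{arr.strand}\t.\tID={aid}.DR{i};Parent={aid}"
            )
        for i, sp in enumerate(arr.spacers, start=1):
            lines.append(
                f"{sid}\tdrscan\tbinding_site\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{arr.strand}\t.\tID={aid}.SP{i};Parent={aid};crispr_role=spacer"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
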