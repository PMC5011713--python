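"""Recovery statistics against a gold-standard CRISPR annotation.

NumDR counts predicted DR copies located within (a slack of) a known
array's span; rDR is NumDR over the known copy number, and may exceed 1
when extra flanking copies are predicted; rCRISPR is the mean rDR over all
known arrays of a genome — the headline accuracy statistic.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .arrays import CRISPRArray
from .io import Interval

DEFAULT_SLACK = 200  # bp; about one DR plus one maximal spacer


class GoldFormatError(ValueError):
    """Raised for malformed gold-standard tables."""


@dataclass
class GoldArray:
    gold_id: str
    seq_id: str
    dr_intervals: list[Interval]

    def __post_init__(self) -> None:
        if len(self.dr_intervals) < 2:
            raise ValueError(f"gold array {self.gold_id} needs >= 2 DR copies")
        self.dr_intervals = sorted(self.dr_intervals, key=lambda iv: iv.start)

    @property
    def n_dr_gold(self) -> int:
        return len(self.dr_intervals)

    @property
    def span(self) -> Interval:
        return Interval(
            self.seq_id, self.dr_intervals[0].start, self.dr_intervals[-1].end
        )


@dataclass
class EvaluationReport:
    per_array: list[tuple[str, int, float]]  # (gold_id, NumDR, rDR)
    r_crispr: float
    n_gold_arrays: int


def num_dr(
    predicted: Sequence[CRISPRArray], gold: GoldArray, slack: int = DEFAULT_SLACK
) -> int:
    """Predicted DR copies whose midpoint falls in the gold span extended by
    ``slack`` on each side; each copy counted at most once."""
    lo = gold.span.start - slack
    hi = gold.span.end + slack
    seen: set[tuple[int, int]] = set()
    count = 0
    for arr in predicted:
        if arr.seq_id != gold.seq_id:
            continue
        for hit in arr.dr_copies:
            key = (hit.location.start, hit.location.end)
            if key in seen:
                continue
            if lo <= hit.location.midpoint() < hi:
                seen.add(key)
                count += 1
    return count


def r_dr(
    predicted: Sequence[CRISPRArray], gold: GoldArray, slack: int = DEFAULT_SLACK
) -> float:
    if gold.n_dr_gold == 0:
        raise ValueError("gold array with zero DR copies")
    return num_dr(predicted, gold, slack) / gold.n_dr_gold


def r_crispr(
    predicted: Sequence[CRISPRArray],
    golds: Sequence[GoldArray],
    slack: int = DEFAULT_SLACK,
) -> float:
    if not golds:
        raise ValueError("r_crispr requires at least one gold array")
    return statistics.fmean(r_dr(predicted, g, slack) for g in golds)


def evaluate(
    predicted: Sequence[CRISPRArray],
    golds: Sequence[GoldArray],
    slack: int = DEFAULT_SLACK,
) -> EvaluationReport:
    per = []
    for g in golds:
        n = num_dr(predicted, g, slack)
        per.append((g.gold_id, n, n / g.n_dr_gold))
    return EvaluationReport(per, statistics.fmean(r[2] for r in per), len(golds))


GOLD_COLUMNS = ["gold_id", "seq_id", "dr_start", "dr_end"]


def read_gold_table(path: str | Path) -> list[GoldArray]:
    """Read a tab-delimited gold table (gold_id, seq_id, dr_start, dr_end;
    1-based inclusive; one row per DR copy), grouped into GoldArrays."""
    path = Path(path)
    groups: dict[str, tuple[str, list[Interval]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (ln == 1 and line.split("\t")[0] == "gold_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GoldFormatError(f"line {ln}: expected 4 columns, got {len(parts)}")
            gid, sid, s_raw, e_raw = parts[:4]
            try:
                start1, end1 = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise GoldFormatError(f"line {ln}: non-integer coordinate") from exc
            if end1 < start1 or start1 < 1:
                raise GoldFormatError(f"line {ln}: invalid coordinates {start1}..{end1}")
            iv = Interval(sid, start1 - 1, end1)  # to 0-based half-open
            if gid in groups and groups[gid][0] != sid:
                raise GoldFormatError(f"line {ln}: gold array {gid} spans multiple records")
            groups.setdefault(gid, (sid, []))[1].append(iv)
    return [GoldArray(gid, sid, ivs) for gid, (sid, ivs) in groups.items()]


def write_gold_table(golds: Sequence[GoldArray], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(GOLD_COLUMNS) + "\n")
        for g in golds:
            for iv in g.dr_intervals:
                fh.write(f"{g.gold_id}\t{g.seq_id}\t{iv.start + 1}\t{iv.end}\n")
    return path


def write_evaluation_report(report: EvaluationReport, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gold_id\tNumDR\trDR\n")
        for gid, n, r in report.per_array:
            fh.write(f"{gid}\t{n}\t{r:.4f}\n")
        fh.write(f"# rCRISPR over {report.n_gold_arrays} arrays: {report.r_crispr:.4f}\n")
    return path
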