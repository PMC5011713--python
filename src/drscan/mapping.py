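"""Mapping template DRs back onto the genome, including degenerate copies.

A representative template is located genome-wide by exact 11-mer seeding
followed by direct (substitution-aware) evaluation of each implied
placement, on both strands.  Truncated copies are reported as partial hits
(prefix or suffix of the template).  A separate rescue scan slides the
template across bounded windows around an existing array — where seeding
has nothing to latch onto — at deliberately permissive identity/coverage
thresholds (0.6 / 0.4), guarded by a binomial-tail significance test so a
random flank cannot produce spurious DR copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.stats import binom

from ._seq import N_CODE, encode, reverse_complement
from .io import GenomeRecord, Interval

MAP_SEED_K = 9  # small enough that a 30-bp copy with 3 substitutions still
# carries an exact seed with high probability; residual misses are caught by
# the window-rescue stages
RESCUE_MIN_IDENTITY = 0.6
RESCUE_MIN_COVERAGE = 0.4
RESCUE_ALPHA = 0.001  # Bonferroni-adjusted binomial tail for rescue acceptance
_MAP_PARTIAL_ALPHA = 0.01  # genome-wide significance bar for partial map hits
_NULL_MATCH_P = 0.25


@dataclass
class MappingConfig:
    map_min_identity: float = 0.8
    map_min_coverage: float = 0.5
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.map_min_identity <= 1 or not 0 < self.map_min_coverage <= 1:
            raise ValueError("identity and coverage thresholds must be in (0, 1]")


@dataclass
class DRHit:
    """One (possibly partial) occurrence of a template DR on the genome."""

    template_id: str
    location: Interval
    identity: float
    coverage: float

    @property
    def is_partial(self) -> bool:
        return self.coverage < 1.0


class KmerIndex:
    """Sorted k-mer code index of one genome record, built once per record."""

    def __init__(self, genome: GenomeRecord, k: int = MAP_SEED_K):
        self.k = k
        from ._seq import kmer_codes

        kcodes, valid = kmer_codes(genome.codes, k)
        kcodes = np.where(valid, kcodes, np.int64(-1))
        self._order = np.argsort(kcodes, kind="stable")
        self._sorted = kcodes[self._order]

    def positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        return self._order[lo:hi]


def _evaluate_offset(
    gcodes: np.ndarray,
    tcodes: np.ndarray,
    s: int,
    min_identity: float,
    min_coverage: float,
) -> tuple[int, int, float, float, int] | None:
    """Evaluate the template aligned at genome offset ``s``.

    Tries the full-length placement first, then truncated (prefix/suffix)
    placements.  Returns (start, end, identity, coverage, n_matches) of the
    best acceptable placement, or None.
    """
    T = len(tcodes)
    n = len(gcodes)
    lo, hi = max(s, 0), min(s + T, n)
    min_len = max(int(ceil(min_coverage * T)), 1)
    if hi - lo < min_len:
        return None
    window = gcodes[lo:hi]
    tpart = tcodes[lo - s : hi - s]
    m = (window == tpart) & (tpart != N_CODE) & (window != N_CODE)
    total = int(np.count_nonzero(m))
    if lo == s and hi == s + T and total / T >= min_identity:
        return (lo, hi, total / T, 1.0, total)
    # truncated placements: the maximal-scoring (matches - mismatches)
    # prefix or suffix of the aligned region, so a truncation is not padded
    # with chance-matching flank columns just to clear the thresholds
    L = hi - lo
    lens = np.arange(1, L + 1)
    best: tuple[int, float, int, int] | None = None  # (aligned_len, identity, start, matches)
    for cum, anchor in ((np.cumsum(m), "p"), (np.cumsum(m[::-1]), "s")):
        score = 2 * cum - lens
        li = int(np.argmax(score))
        alen, matches = li + 1, int(cum[li])
        ident = matches / alen
        if alen < min_len or ident < min_identity:
            continue
        start = lo if anchor == "p" else hi - alen
        cand = (alen, ident, start, matches)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        return None
    alen, ident, start, matches = best
    return (start, start + alen, ident, alen / T, matches)


def _greedy_select(
    candidates: list[tuple[int, int, float, float, str]],
    template_len: int,
    seq_id: str,
    template_id: str,
) -> list[DRHit]:
    """Best-identity-first selection; accepted hits may overlap by at most
    half the template length."""
    max_overlap = template_len // 2
    candidates = sorted(candidates, key=lambda c: (-c[2], -(c[1] - c[0]), c[0]))
    accepted: list[tuple[int, int]] = []
    hits: list[DRHit] = []
    for start, end, ident, cov, strand in candidates:
        ok = True
        for a, b in accepted:
            ov = min(end, b) - max(start, a)
            if ov > max_overlap or (start, end) == (a, b):
                ok = False
                break
        if not ok:
            continue
        accepted.append((start, end))
        hits.append(DRHit(template_id, Interval(seq_id, start, end, strand), ident, cov))
    hits.sort(key=lambda h: h.location.start)
    return hits


def map_template(
    genome: GenomeRecord,
    template: str,
    config: MappingConfig | None = None,
    index: KmerIndex | None = None,
    template_id: str = "T?",
) -> list[DRHit]:
    """All placements of a template (and its reverse complement) with
    identity >= map_min_identity over >= map_min_coverage of its length."""
    config = config or MappingConfig()
    if template.count("N") > len(template) / 2:
        raise ValueError("template is more than 50% N")
    index = index or KmerIndex(genome)
    gcodes = genome.codes
    T = len(template)
    strands = [("+", template)]
    if config.search_both_strands:
        strands.append(("-", reverse_complement(template)))

    candidates: list[tuple[int, int, float, float, str]] = []
    for strand, tseq in strands:
        tcodes = encode(tseq)
        from ._seq import kmer_codes

        seed_codes, seed_valid = kmer_codes(tcodes, index.k)
        offsets: set[int] = set()
        for t_off in range(len(seed_codes)):
            if not seed_valid[t_off]:
                continue
            for g in index.positions(int(seed_codes[t_off])):
                offsets.add(int(g) - t_off)
        for s in sorted(offsets):
            ev = _evaluate_offset(
                gcodes, tcodes, s, config.map_min_identity, config.map_min_coverage
            )
            if ev is None:
                continue
            start, end, ident, cov, matches = ev
            if cov < 1.0:
                # a truncated placement carries fewer matching columns, so
                # it must be genome-wide significant to count as a copy
                p = float(binom.sf(matches - 1, end - start, _NULL_MATCH_P))
                if p * 2 * len(gcodes) > _MAP_PARTIAL_ALPHA:
                    continue
            candidates.append((start, end, ident, cov, strand))
    return _greedy_select(candidates, T, genome.seq_id, template_id)


def scan_window(
    genome: GenomeRecord,
    template: str,
    win_start: int,
    win_end: int,
    strand: str = "+",
    min_identity: float = RESCUE_MIN_IDENTITY,
    min_coverage: float = RESCUE_MIN_COVERAGE,
    alpha: float = RESCUE_ALPHA,
    template_id: str = "T?",
) -> list[DRHit]:
    """Slide a template across a window; keep statistically significant
    placements clearing the (permissive) rescue thresholds."""
    win_start = max(0, win_start)
    win_end = min(genome.length, win_end)
    T = len(template)
    min_len = max(int(ceil(min_coverage * T)), 1)
    if win_end - win_start < min_len:
        return []
    tseq = template if strand == "+" else reverse_complement(template)
    tcodes = encode(tseq)
    gcodes = genome.codes
    offsets = range(win_start - (T - min_len), win_end - min_len + 1)
    n_offsets = max(len(offsets), 1)
    # a truncated placement additionally chooses its anchor (prefix/suffix);
    # the aligned length is fixed by the max-score rule, not tail-optimized
    n_trials_partial = n_offsets * 2
    found: list[tuple[int, int, float, float, str]] = []
    for s in offsets:
        ev = _evaluate_offset(gcodes, tcodes, s, min_identity, min_coverage)
        if ev is None:
            continue
        start, end, ident, cov, matches = ev
        if start < win_start or end > win_end:
            continue
        alen = end - start
        p = float(binom.sf(matches - 1, alen, _NULL_MATCH_P))
        n_trials = n_offsets if cov >= 1.0 else n_trials_partial
        if p * n_trials > alpha:
            continue
        found.append((start, end, ident, cov, strand))
    return _greedy_select(found, T, genome.seq_id, template_id)


def rescue_partial_hits(
    genome: GenomeRecord,
    template: str,
    anchor_hits: list[DRHit],
    config: MappingConfig | None = None,
    spacer_min: int = 10,
    spacer_max: int = 120,
) -> list[DRHit]:
    """Screen the flanks of the first/last anchor and long inter-hit gaps
    for DR copies missed by seeded mapping; never overlaps an anchor."""
    if not anchor_hits:
        raise ValueError("rescue requires at least one anchor hit")
    config = config or MappingConfig()
    anchors = sorted(anchor_hits, key=lambda h: h.location.start)
    strand = anchors[0].location.strand
    template_id = anchors[0].template_id
    T = len(template)

    windows: list[tuple[int, int]] = [
        (anchors[0].location.start - (T + spacer_max), anchors[0].location.start),
        (anchors[-1].location.end, anchors[-1].location.end + T + spacer_max),
    ]
    for prev, nxt in zip(anchors, anchors[1:]):
        gap = nxt.location.start - prev.location.end
        if gap >= T * RESCUE_MIN_COVERAGE + 2 * spacer_min:
            windows.append((prev.location.end, nxt.location.start))

    rescued: list[DRHit] = []
    occupied = [(h.location.start, h.location.end) for h in anchors]
    for ws, we in windows:
        for hit in scan_window(
            genome, template, ws, we, strand=strand, template_id=template_id
        ):
            loc = hit.location
            if any(loc.start < b and a < loc.end for a, b in occupied):
                continue
            occupied.append((loc.start, loc.end))
            rescued.append(hit)
    out = anchors + rescued
    out.sort(key=lambda h: h.location.start)
    return out
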