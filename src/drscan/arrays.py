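"""Assembly of DR hits into CRISPR arrays and their refinement.

Consecutive hits of one template on one strand are chained into candidate
arrays when the gap between them (the spacer) falls in the allowed length
band.  Candidates are then refined: closely spaced same-template arrays are
merged after re-scanning the gap for a degenerate internal DR; arrays whose
spacers are mutually similar are discarded as false positives (true spacers
are acquired independently and should not resemble one another); termini
are extended by rescuing divergent or truncated terminal DR copies; and
overlapping candidates are combined before final filtering.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._seq import BASES, N_CODE, encode, reverse_complement, trim_weak_ends
from .clustering import similarity_ratio
from .io import GenomeRecord, Interval
from .mapping import DRHit, MappingConfig, rescue_partial_hits, scan_window

_TRIM_AGREEMENT = 0.7  # permissive pivot for trimming weak terminal consensus columns
_TRIM_AGREEMENT_STRICT = 0.85  # strict pivot used first during finalization
_MAX_EXTEND_ROUNDS = 64


@dataclass
class ArrayConfig:
    spacer_min_len: int = 10
    spacer_max_len: int = 120
    min_dr_copies: int = 3
    spacer_similarity_threshold: float = 0.5
    dr_final_min: int = 23
    dr_final_max: int = 55

    def __post_init__(self) -> None:
        if not self.spacer_min_len < self.spacer_max_len:
            raise ValueError("spacer_min_len must be < spacer_max_len")
        if self.min_dr_copies < 2:
            raise ValueError("min_dr_copies must be >= 2")


@dataclass
class CRISPRArray:
    """An ordered alternation of DR copies and spacers with a consensus DR."""

    array_id: str
    seq_id: str
    template_id: str
    consensus_dr: str
    dr_copies: list[DRHit]
    strand: str = "+"
    dr_sequences: list[str] = field(default_factory=list)
    spacer_sequences: list[str] = field(default_factory=list)
    dr_identities: list[float] = field(default_factory=list)
    mean_identity: float = 0.0

    @property
    def n_dr(self) -> int:
        return len(self.dr_copies)

    @property
    def n_spacer(self) -> int:
        return max(self.n_dr - 1, 0)

    @property
    def span(self) -> Interval:
        return Interval(
            self.seq_id, self.dr_copies[0].location.start, self.dr_copies[-1].location.end,
            self.strand,
        )

    @property
    def spacers(self) -> list[Interval]:
        out = []
        for prev, nxt in zip(self.dr_copies, self.dr_copies[1:]):
            out.append(Interval(self.seq_id, prev.location.end, nxt.location.start, self.strand))
        return out


def assemble_arrays(
    hits: list[DRHit],
    config: ArrayConfig | None = None,
    consensus_dr: str = "",
    seq_id: str | None = None,
) -> list[CRISPRArray]:
    """Greedy left-to-right chaining of sorted, non-overlapping hits.

    A gap inside [spacer_min_len, spacer_max_len] continues the current
    array; any other gap closes it.  Arrays below min_dr_copies are kept
    provisionally (merging/extension may still grow them); finalize() drops
    the ones that stay short.
    """
    config = config or ArrayConfig()
    if not hits:
        return []
    for prev, nxt in zip(hits, hits[1:]):
        if nxt.location.start < prev.location.end:
            raise ValueError("assemble_arrays requires sorted non-overlapping hits")
    sid = seq_id or hits[0].location.seq_id
    strand = hits[0].location.strand
    template_id = hits[0].template_id
    chains: list[list[DRHit]] = [[hits[0]]]
    for prev, nxt in zip(hits, hits[1:]):
        gap = nxt.location.start - prev.location.end
        if config.spacer_min_len <= gap <= config.spacer_max_len:
            chains[-1].append(nxt)
        else:
            chains.append([nxt])
    return [
        CRISPRArray("?", sid, template_id, consensus_dr, chain, strand) for chain in chains
    ]


def merge_same_template(
    arrays: list[CRISPRArray],
    genome: GenomeRecord,
    config: ArrayConfig | None = None,
    map_config: MappingConfig | None = None,
) -> list[CRISPRArray]:
    """Merge adjacent same-template arrays separated by at most one DR plus
    two (maximal) spacers, re-scanning the gap for a degenerate DR copy."""
    config = config or ArrayConfig()
    arrays = sorted(arrays, key=lambda a: a.span.start)
    changed = True
    while changed:
        changed = False
        for i in range(len(arrays) - 1):
            a, b = arrays[i], arrays[i + 1]
            if (
                a.template_id != b.template_id
                or a.strand != b.strand
                or a.seq_id != b.seq_id
            ):
                continue
            gap = b.span.start - a.span.end
            max_gap = 2 * config.spacer_max_len + len(a.consensus_dr or b.consensus_dr)
            if gap < 0 or gap > max_gap:
                continue
            template = a.consensus_dr or b.consensus_dr
            rescued = (
                scan_window(
                    genome, template, a.span.end, b.span.start,
                    strand=a.strand, template_id=a.template_id,
                )
                if template
                else []
            )
            combined = sorted(
                a.dr_copies + b.dr_copies + rescued, key=lambda h: h.location.start
            )
            rebuilt = assemble_arrays(combined, config, template, a.seq_id)
            if len(rebuilt) == 1:
                arrays[i : i + 2] = rebuilt
                changed = True
                break
            # without the rescued copy the pair may still chain directly
            rebuilt = assemble_arrays(
                sorted(a.dr_copies + b.dr_copies, key=lambda h: h.location.start),
                config, template, a.seq_id,
            )
            if len(rebuilt) == 1:
                arrays[i : i + 2] = rebuilt
                changed = True
                break
    return arrays


def _spacer_seqs(array: CRISPRArray, genome: GenomeRecord) -> list[str]:
    seqs = [genome.sequence[s.start : s.end] for s in array.spacers]
    if array.strand == "-":
        seqs = [reverse_complement(s) for s in reversed(seqs)]
    return seqs


def spacer_false_positive_filter(
    array: CRISPRArray, genome: GenomeRecord, config: ArrayConfig | None = None
) -> tuple[bool, str]:
    """Keep-or-discard decision by mean pairwise spacer similarity.

    True spacers are independent acquisitions; a candidate whose spacers are
    mutually similar is a tandem-like false positive.  Arrays with fewer
    than two spacers are kept (the test is undefined for them).  Returns
    (keep, reason)."""
    config = config or ArrayConfig()
    if array.n_spacer < 2:
        return True, "fewer than 2 spacers; similarity test not applicable"
    seqs = _spacer_seqs(array, genome)
    sims = []
    offending = []
    for (i, a), (j, b) in combinations(enumerate(seqs), 2):
        s = similarity_ratio(a, b)
        sims.append(s)
        if s > config.spacer_similarity_threshold:
            offending.append((i + 1, j + 1, round(s, 3)))
    mean = statistics.fmean(sims)
    if mean > config.spacer_similarity_threshold:
        return False, f"mean pairwise spacer similarity {mean:.3f} > {config.spacer_similarity_threshold}; pairs over threshold: {offending}"
    return True, f"mean pairwise spacer similarity {mean:.3f}"


def rescue_internal(
    array: CRISPRArray,
    genome: GenomeRecord,
    config: ArrayConfig | None = None,
    map_config: MappingConfig | None = None,
) -> CRISPRArray:
    """Re-scan long inter-DR gaps of one array for copies missed by seeded
    mapping.  A copy is inserted only when both induced spacers stay inside
    the allowed length band, so the alternation invariant is preserved."""
    config = config or ArrayConfig()
    template = array.consensus_dr
    if not template or array.n_dr < 2:
        return array
    T = len(template)
    min_gap = 2 * config.spacer_min_len + int(T * 0.4)
    hits = list(array.dr_copies)
    changed = True
    while changed:
        changed = False
        for i in range(len(hits) - 1):
            gap_start, gap_end = hits[i].location.end, hits[i + 1].location.start
            if gap_end - gap_start < min_gap:
                continue
            for cand in scan_window(
                genome, template, gap_start, gap_end,
                strand=array.strand, template_id=array.template_id,
            ):
                left = cand.location.start - gap_start
                right = gap_end - cand.location.end
                if (
                    config.spacer_min_len <= left <= config.spacer_max_len
                    and config.spacer_min_len <= right <= config.spacer_max_len
                ):
                    hits.insert(i + 1, cand)
                    changed = True
                    break
            if changed:
                break
    array.dr_copies = hits
    return array


def extend_termini(
    array: CRISPRArray,
    genome: GenomeRecord,
    config: ArrayConfig | None = None,
    map_config: MappingConfig | None = None,
) -> CRISPRArray:
    """Rescue missed terminal DR copies from the flanking windows until no
    further copy is accepted; each accepted copy must leave a spacer inside
    the allowed length band."""
    config = config or ArrayConfig()
    template = array.consensus_dr
    if not template:
        return array
    T = len(template)
    hits = list(array.dr_copies)
    for _ in range(_MAX_EXTEND_ROUNDS):
        grew = False
        first, last = hits[0], hits[-1]
        up = scan_window(
            genome, template,
            first.location.start - (T + config.spacer_max_len), first.location.start,
            strand=array.strand, template_id=array.template_id,
        )
        for cand in sorted(up, key=lambda h: -h.location.end):
            spacer = first.location.start - cand.location.end
            if config.spacer_min_len <= spacer <= config.spacer_max_len:
                hits.insert(0, cand)
                grew = True
                break
        down = scan_window(
            genome, template,
            last.location.end, last.location.end + T + config.spacer_max_len,
            strand=array.strand, template_id=array.template_id,
        )
        for cand in sorted(down, key=lambda h: h.location.start):
            spacer = cand.location.start - last.location.end
            if config.spacer_min_len <= spacer <= config.spacer_max_len:
                hits.append(cand)
                grew = True
                break
        if not grew:
            break
    array.dr_copies = hits
    return array


def _oriented_copy_codes(hit: DRHit, genome: GenomeRecord, strand: str) -> np.ndarray:
    seq = genome.sequence[hit.location.start : hit.location.end]
    if strand == "-":
        seq = reverse_complement(seq)
    return encode(seq)


def _recompute_consensus(array: CRISPRArray, genome: GenomeRecord, config: ArrayConfig) -> None:
    """Column-majority consensus over full-length copies, trimming terminal
    columns with weak support (flank bases dragged in by over-extension)."""
    full = [h for h in array.dr_copies if not h.is_partial]
    if not full:
        return
    length = full[0].location.length()
    mats = [
        _oriented_copy_codes(h, genome, array.strand)
        for h in full
        if h.location.length() == length
    ]
    if not mats:
        return
    M = np.stack(mats)
    cons = np.empty(length, dtype=np.uint8)
    agree = np.empty(length)
    for j in range(length):
        col = M[:, j]
        bc = np.bincount(col[col != N_CODE], minlength=4)
        if bc.sum() == 0:
            cons[j], agree[j] = N_CODE, 0.0
        else:
            cons[j] = int(np.argmax(bc))
            agree[j] = bc[cons[j]] / len(col)
    # strict pivot first: extension over-runs are enriched for terminal
    # columns that agree by chance, so a permissive pivot can miss the run;
    # fall back to the permissive pivot if the strict one would cut the
    # consensus below the minimum DR length
    lo, hi = trim_weak_ends(agree, _TRIM_AGREEMENT_STRICT)
    if hi - lo < config.dr_final_min:
        lo, hi = trim_weak_ends(agree, _TRIM_AGREEMENT)
    # over-length consensus: shed weakly supported terminal columns (flank
    # bases dragged in by over-extension); a genuinely repeated long
    # terminal column (support >= 0.8) is kept, so true out-of-band repeats
    # still fail the final length filter
    while hi - lo > config.dr_final_max and min(agree[lo], agree[hi - 1]) < 0.8:
        if agree[lo] <= agree[hi - 1]:
            lo += 1
        else:
            hi -= 1
    if hi - lo == 0:
        return
    array.consensus_dr = "".join(BASES[c] for c in cons[lo:hi])
    if lo or hi < length:
        trimmed = []
        for h in array.dr_copies:
            loc = h.location
            if h.is_partial or loc.length() != length:
                trimmed.append(h)
                continue
            if array.strand == "+":
                ival = Interval(loc.seq_id, loc.start + lo, loc.start + hi, loc.strand)
            else:
                ival = Interval(loc.seq_id, loc.end - hi, loc.end - lo, loc.strand)
            trimmed.append(DRHit(h.template_id, ival, h.identity, h.coverage))
        array.dr_copies = trimmed
    # an under-length consensus (a genuine boundary column lost upstream)
    # is grown back outward while the adjacent genome column is strongly
    # supported across the copies; random flanks never qualify
    while len(array.consensus_dr) < config.dr_final_min:
        if not _grow_one_column(array, genome):
            break


def _grow_one_column(array: CRISPRArray, genome: GenomeRecord) -> bool:
    """Extend every full-length DR copy by one base on whichever side shows
    the stronger cross-copy agreement (if >= 0.7); returns False when
    neither side qualifies or a copy would leave the genome."""
    full = [h for h in array.dr_copies if not h.is_partial]
    if not full:
        return False
    length = max(h.location.length() for h in full)
    full = [h for h in full if h.location.length() == length]

    def column(side: str) -> tuple[float, int] | None:
        bases = []
        for h in full:
            loc = h.location
            outward_left = (side == "front") == (array.strand == "+")
            p = loc.start - 1 if outward_left else loc.end
            if not 0 <= p < genome.length:
                return None
            c = genome.codes[p]
            if array.strand == "-" and c != N_CODE:
                c = 3 - c
            bases.append(int(c))
        arr = np.asarray(bases)
        bc = np.bincount(arr[arr != N_CODE], minlength=4)
        if bc.sum() == 0:
            return None
        best = int(np.argmax(bc))
        return bc[best] / len(full), best

    cands = [(side, column(side)) for side in ("front", "back")]
    cands = [(s, c) for s, c in cands if c is not None and c[0] >= _TRIM_AGREEMENT]
    if not cands:
        return False
    side, (agree, base) = max(cands, key=lambda sc: sc[1][0])
    grown = []
    for h in array.dr_copies:
        loc = h.location
        if h.is_partial or loc.length() != length:
            grown.append(h)
            continue
        outward_left = (side == "front") == (array.strand == "+")
        if outward_left:
            ival = Interval(loc.seq_id, loc.start - 1, loc.end, loc.strand)
        else:
            ival = Interval(loc.seq_id, loc.start, loc.end + 1, loc.strand)
        grown.append(DRHit(h.template_id, ival, h.identity, h.coverage))
    array.dr_copies = grown
    if side == "front":
        array.consensus_dr = BASES[base] + array.consensus_dr
    else:
        array.consensus_dr = array.consensus_dr + BASES[base]
    return True


def _attach_sequences(array: CRISPRArray, genome: GenomeRecord) -> None:
    cons = encode(array.consensus_dr)
    seqs, idents = [], []
    for h in array.dr_copies:
        codes = _oriented_copy_codes(h, genome, array.strand)
        seqs.append("".join(BASES[c] for c in codes))
        if len(codes) == len(cons):
            m = (codes == cons) & (codes != N_CODE)
            idents.append(float(np.count_nonzero(m)) / len(cons))
        else:
            idents.append(h.identity)
    array.dr_sequences = seqs
    array.dr_identities = idents
    array.mean_identity = statistics.fmean(idents) if idents else 0.0
    array.spacer_sequences = [
        genome.sequence[s.start : s.end] for s in array.spacers
    ]
    if array.strand == "-":
        array.spacer_sequences = [
            reverse_complement(s) for s in array.spacer_sequences
        ]


def finalize(
    arrays: list[CRISPRArray],
    genome: GenomeRecord,
    config: ArrayConfig | None = None,
    map_config: MappingConfig | None = None,
) -> list[CRISPRArray]:
    """Combine overlapping candidates, re-merge close same-template arrays,
    apply the final copy-number and DR-length filters, recompute the
    consensus, and assign genomic-order array IDs."""
    config = config or ArrayConfig()
    pool = [a for a in arrays if a.n_dr > 0]
    # consensus update and DR-length band first: an array whose consensus
    # cannot be brought into the band (e.g. built from a short fragment of
    # the true DR) must not absorb a viable overlapping array and then be
    # dropped, taking the locus with it
    banded = []
    for a in pool:
        _recompute_consensus(a, genome, config)
        if config.dr_final_min <= len(a.consensus_dr) <= config.dr_final_max:
            banded.append(a)
    # overlapping arrays: more DR copies absorbs; ties by identity, then leftmost
    def _mean_ident(a: CRISPRArray) -> float:
        return statistics.fmean(h.identity for h in a.dr_copies)

    banded.sort(key=lambda a: (-a.n_dr, -_mean_ident(a), a.span.start))
    kept: list[CRISPRArray] = []
    kept_spans: dict[str, list[tuple[int, int]]] = {}
    for a in banded:
        sp = a.span
        if all(
            not (sp.start < e and s < sp.end) for s, e in kept_spans.get(a.seq_id, ())
        ):
            kept.append(a)
            kept_spans.setdefault(a.seq_id, []).append((sp.start, sp.end))
    # close-proximity same-template merging re-applied across the pool
    kept = merge_same_template(kept, genome, config, map_config)
    # final copy-number filter, sequence extraction, genomic-order IDs
    final = []
    for a in kept:
        if a.n_dr < config.min_dr_copies:
            continue
        _recompute_consensus(a, genome, config)
        if not config.dr_final_min <= len(a.consensus_dr) <= config.dr_final_max:
            continue
        _attach_sequences(a, genome)
        final.append(a)
    final.sort(key=lambda a: (a.seq_id, a.span.start))
    for i, a in enumerate(final, start=1):
        a.array_id = f"CRISPR{i}"
    return final
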