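"""De novo discovery of direct-repeat-like templates.

A seed-and-extend finder constrained to the DR length band replaces a
general interspersed-repeat screen: exact seed k-mers occurring at least
``min_copies`` times are grouped and each group is extended column by
column.  Per column the majority base becomes the consensus; the column
score 2*maxcount - n_copies - 1 has negative drift on random sequence and
strongly positive drift inside a conserved repeat, so an X-drop rule with
trim-back-to-maximum stops extension at the repeat boundary.  Copies whose
overall agreement with the consensus falls below 80% are dropped; a
template is kept only while at least ``min_copies`` copies remain.

Low-complexity and short-period tandem templates (microsatellites) are
removed by an entropy filter and a periodicity test; the entropy cutoff is
deliberately permissive so genuinely low-complexity DRs survive.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import N_CODE, decode, kmer_codes, trim_weak_ends
from .io import GenomeRecord, Interval

_EXTEND_AGREEMENT = 0.8  # per-copy identity floor against the consensus
_XDROP = 8  # stop a direction when cumulative column score drops this far below its max
_MAX_GROUP_COPIES = 200  # cap pathological seed groups (e.g. huge homopolymer runs)
_TRIM_PIVOT = 0.85  # agreement pivot for trimming over-extended template ends;
# strict, because over-extension is enriched for columns agreeing by chance
_TRIM_PIVOT_VERIFIED = 0.7  # pivot for the re-trim against verified copies
_SEED_MIN_OCC = 2  # seed groups may start from a pair; templates are then
# verified by re-locating the consensus genome-wide, so the emitted
# copy_count >= min_copies invariant still holds.  Pair seeding matters for
# small diverged arrays where no k-mer is jointly unmutated in >= 3 copies.


@dataclass
class DiscoveryConfig:
    """Knobs of the template-discovery stage (defaults follow the DR band)."""

    template_min_len: int = 15
    template_max_len: int = 60
    seed_k: int = 15
    min_copies: int = 3
    complexity_threshold: float = 0.9
    tandem_period_max: int = 6
    tandem_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.seed_k <= self.template_min_len <= self.template_max_len:
            raise ValueError("require seed_k <= template_min_len <= template_max_len")
        if not 0 < self.complexity_threshold <= 1:
            raise ValueError("complexity_threshold must be in (0, 1]")


@dataclass
class RepeatTemplate:
    """A candidate DR consensus with the genomic locations of its copies."""

    template_id: str
    consensus: str
    copies: list[Interval] = field(default_factory=list)

    @property
    def copy_count(self) -> int:
        return len(self.copies)


def complexity_score(seq: str) -> float:
    """Shannon entropy of the mononucleotide composition, normalized to [0,1].

    2 bits (a uniform 4-letter composition) maps to 1.0.  N is excluded;
    an all-N sequence scores 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(c for c in seq if c != "N")
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return h / 2.0


def is_tandem_periodic(seq: str, config: DiscoveryConfig | None = None) -> bool:
    """True iff the sequence is itself a short tandem repeat (period <= 6)."""
    config = config or DiscoveryConfig()
    if not seq:
        raise ValueError("empty sequence")
    for p in range(1, config.tandem_period_max + 1):
        if len(seq) <= p:
            break
        n = len(seq) - p
        matches = sum(
            1 for i in range(n) if seq[i] == seq[i + p] and seq[i] != "N"
        )
        if matches / n >= config.tandem_fraction:
            return True
    return False


def _thin_positions(positions: np.ndarray, min_gap: int) -> list[int]:
    """Greedy left-to-right selection keeping positions >= min_gap apart."""
    kept: list[int] = []
    for p in positions:
        if not kept or p - kept[-1] >= min_gap:
            kept.append(int(p))
    return kept


def _extend_group(
    codes: np.ndarray, positions: list[int], k: int, config: DiscoveryConfig
) -> tuple[int, int, np.ndarray, list[int]] | None:
    """Extend a seed group left and right; returns (left_ext, right_ext,
    consensus_codes, surviving_positions) or None."""
    n_genome = len(codes)
    max_total = config.template_max_len
    pos = np.asarray(positions, dtype=np.int64)

    min_group = min(config.min_copies, _SEED_MIN_OCC)

    def direction(sign: int, budget: int) -> tuple[int, list[int]]:
        # sign=+1 extends right of the seed, -1 extends left
        best, cum, ext = 0, 0.0, 0
        cons: list[int] = []
        best_cons_len = 0
        for step in range(1, budget + 1):
            off = k - 1 + step if sign > 0 else -step
            idx = pos + off
            valid = (idx >= 0) & (idx < n_genome)
            col = np.where(valid, codes[np.clip(idx, 0, n_genome - 1)], N_CODE)
            bc = np.bincount(col[col != N_CODE], minlength=4)
            if bc.sum() == 0:
                break
            maxbase = int(np.argmax(bc))
            maxcount = int(bc[maxbase])
            cum += 2 * maxcount - len(pos) - 1
            cons.append(maxbase)
            if cum > best:
                best, ext = cum, step
                best_cons_len = len(cons)
            elif cum <= best - _XDROP:
                break
        return ext, cons[:best_cons_len]

    right_budget = max_total - k
    right_ext, right_cons = direction(+1, right_budget)
    left_budget = max_total - k - right_ext
    left_ext, left_cons = direction(-1, left_budget)

    length = k + left_ext + right_ext
    consensus = np.concatenate(
        [
            np.asarray(left_cons[::-1], dtype=np.uint8),
            codes[positions[0] : positions[0] + k],
            np.asarray(right_cons, dtype=np.uint8),
        ]
    )
    # trim terminal columns weakly supported across copies (over-extension
    # into flanking sequence survives the X-drop occasionally); permissive
    # pivot — for 2-4 diverged copies the agreement quantization makes a
    # strict pivot eat genuine columns, and the verification re-trim plus
    # finalization settle boundaries anyway
    starts = pos - left_ext
    ok = (starts >= 0) & (starts + length <= n_genome)
    if ok.any():
        M = np.stack([codes[s : s + length] for s in starts[ok]])
        agree = np.mean((M == consensus) & (M != N_CODE), axis=0)
        lo, hi = trim_weak_ends(agree, _TRIM_PIVOT_VERIFIED)
        if hi - lo == 0:
            return None
        consensus = consensus[lo:hi]
        left_ext -= lo
        length = hi - lo
    # per-copy agreement filter over the full template
    survivors: list[int] = []
    for p in positions:
        s, e = p - left_ext, p - left_ext + length
        if s < 0 or e > n_genome:
            continue
        window = codes[s:e]
        ident = np.count_nonzero((window == consensus) & (window != N_CODE)) / length
        if ident >= _EXTEND_AGREEMENT:
            survivors.append(s)
    if len(survivors) < min_group:
        return None
    return left_ext, right_ext, consensus, survivors


def _retrim_verified(
    codes: np.ndarray, cons: str, copies: list[Interval], seq_id: str
) -> tuple[str, list[Interval]]:
    """Majority consensus over the verified copies with strict terminal
    trimming; returns the updated consensus and shifted copy intervals."""
    length = len(cons)
    M = np.stack([codes[c.start : c.end] for c in copies])
    new_cons = np.empty(length, dtype=np.uint8)
    agree = np.empty(length)
    for j in range(length):
        col = M[:, j]
        bc = np.bincount(col[col != N_CODE], minlength=4)
        if bc.sum() == 0:
            new_cons[j], agree[j] = N_CODE, 0.0
        else:
            new_cons[j] = int(np.argmax(bc))
            agree[j] = bc[new_cons[j]] / len(col)
    # permissive pivot: the verified copies are located independently, so
    # flank columns agree only at chance levels (plus at most the two
    # seed copies); a strict pivot here would eat genuine columns of highly
    # diverged repeats
    lo, hi = trim_weak_ends(agree, _TRIM_PIVOT_VERIFIED)
    if hi - lo <= 0:
        return "", []
    return (
        decode(new_cons[lo:hi]),
        [Interval(seq_id, c.start + lo, c.start + hi) for c in copies],
    )


def find_repeat_templates(
    genome: GenomeRecord, config: DiscoveryConfig | None = None, index=None
) -> list[RepeatTemplate]:
    """Enumerate seed k-mer groups and extend them into repeat templates.

    Templates whose consensus length falls outside
    [template_min_len, template_max_len] are not emitted; groups extending
    to the same consensus are deduplicated (copy sets merged).
    """
    config = config or DiscoveryConfig()
    codes = genome.codes
    if genome.length < config.seed_k:
        return []
    kcodes, valid = kmer_codes(codes, config.seed_k)
    if len(kcodes) == 0:
        return []
    kcodes = np.where(valid, kcodes, -1)
    order = np.argsort(kcodes, kind="stable")
    sorted_codes = kcodes[order]
    # run boundaries of equal codes
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(sorted_codes)]])

    min_group = min(config.min_copies, _SEED_MIN_OCC)
    groups: list[list[int]] = []
    for s, e in zip(starts, ends):
        if e - s < min_group or sorted_codes[s] < 0:
            continue
        positions = np.sort(order[s:e])
        thinned = _thin_positions(positions, config.seed_k)
        if len(thinned) < min_group:
            continue
        groups.append(thinned[:_MAX_GROUP_COPIES])
    groups.sort(key=lambda g: g[0])

    by_consensus: dict[str, list[Interval]] = {}
    for g in groups:
        ext = _extend_group(codes, g, config.seed_k, config)
        if ext is None:
            continue
        _, _, consensus, survivors = ext
        length = len(consensus)
        if not config.template_min_len <= length <= config.template_max_len:
            continue
        cons_str = decode(consensus)
        copies = by_consensus.setdefault(cons_str, [])
        for s in survivors:
            iv = Interval(genome.seq_id, s, s + length)
            if all(not iv.overlaps(c) for c in copies):
                copies.append(iv)

    # verify every candidate consensus by re-locating it genome-wide
    # (forward strand); this both confirms pair-seeded templates and
    # completes copy sets the seed groups under-reported
    from .mapping import KmerIndex, MappingConfig, map_template

    index = index or KmerIndex(genome)
    # two-round verification: a pair-derived consensus carries roughly the
    # per-copy divergence in errors, leaving true copies at the identity
    # floor; a loose first round collects copies, the majority consensus is
    # rebuilt from them, and the final round applies the real floor
    loose_cfg = MappingConfig(
        map_min_identity=0.75, map_min_coverage=1.0, search_both_strands=False
    )
    map_cfg = MappingConfig(
        map_min_identity=_EXTEND_AGREEMENT, map_min_coverage=1.0, search_both_strands=False
    )
    candidates: list[tuple[float, RepeatTemplate]] = []
    items = sorted(by_consensus.items(), key=lambda kv: min(c.start for c in kv[1]))
    fine_index: list = [None]  # lazily built small-seed index

    def _best_hits(cons: str, cfg, idx=None) -> list:
        hits = map_template(genome, cons, cfg, idx or index)
        chosen = []
        for h in sorted(hits, key=lambda h: -h.identity):
            if all(not h.location.overlaps(c.location) for c in chosen):
                chosen.append(h)
        chosen.sort(key=lambda h: h.location.start)
        return chosen

    for cons, copies in items:
        rough = _best_hits(cons, loose_cfg)
        if len(rough) < config.min_copies and len(cons) >= 20:
            # highly diverged copies of a pair consensus may carry no exact
            # default-size seed; retry with a small-seed index (long
            # candidates only — chance pairs rarely extend this far)
            if fine_index[0] is None:
                fine_index[0] = KmerIndex(genome, k=7)
            rough = _best_hits(cons, loose_cfg, fine_index[0])
        if len(rough) < config.min_copies:
            continue
        # rebuild the consensus from the collected copies; this also trims
        # flank bases the two seed copies shared by chance, which only the
        # full copy set reveals as unsupported
        cons, _ = _retrim_verified(
            codes, cons, [h.location for h in rough], genome.seq_id
        )
        if not config.template_min_len <= len(cons) <= config.template_max_len:
            continue
        chosen = _best_hits(cons, map_cfg)
        if len(chosen) < config.min_copies:
            continue
        mean_ident = sum(h.identity for h in chosen) / len(chosen)
        candidates.append(
            (mean_ident, RepeatTemplate("?", cons, [h.location for h in chosen]))
        )

    # pair-seeded groups sharing chance flank bases yield boundary-shifted
    # variants of one repeat; keep the best-supported template per copy set
    def _covered(t: RepeatTemplate, kept: RepeatTemplate) -> bool:
        n_cov = 0
        for c in t.copies:
            for k in kept.copies:
                ov = min(c.end, k.end) - max(c.start, k.start)
                if ov >= 0.5 * min(c.length(), k.length()):
                    n_cov += 1
                    break
        return n_cov >= 0.8 * len(t.copies)

    # prefer the template explaining the most sequence per copy (identity x
    # length): a short exact fragment of a diverged repeat must not shadow
    # the full-length template
    candidates.sort(
        key=lambda mi_t: (
            -mi_t[0] * len(mi_t[1].consensus),
            len(mi_t[1].consensus),
            mi_t[1].consensus,
        )
    )
    templates: list[RepeatTemplate] = []
    for _, t in candidates:
        if not any(_covered(t, k) for k in templates):
            templates.append(t)
    templates.sort(key=lambda t: t.copies[0].start)
    for i, t in enumerate(templates):
        t.template_id = f"T{i + 1}"
    return templates


def filter_templates(
    templates: list[RepeatTemplate], config: DiscoveryConfig | None = None
) -> list[RepeatTemplate]:
    """Drop low-complexity, tandem-periodic, and out-of-band templates.

    The entropy cutoff is 1 - complexity_threshold (default 0.1), so only
    near-homopolymers are removed and low-complexity DRs survive.
    """
    config = config or DiscoveryConfig()
    kept = []
    for t in templates:
        if not config.template_min_len <= len(t.consensus) <= config.template_max_len:
            continue
        if complexity_score(t.consensus) < (1.0 - config.complexity_threshold):
            continue
        if is_tandem_periodic(t.consensus, config):
            continue
        kept.append(t)
    return kept
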