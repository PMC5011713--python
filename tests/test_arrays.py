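import numpy as np
import pytest

from drscan import (
    ArrayConfig,
    GenomeRecord,
    assemble_arrays,
    detect_record,
    extend_termini,
    finalize,
    merge_same_template,
    spacer_false_positive_filter,
)
from drscan.arrays import CRISPRArray
from drscan.mapping import DRHit
from drscan.io import Interval

from conftest import plant_exact, random_seq


def mk_hits(starts, length=30, template_id="T1", seq_id="g"):
    return [
        DRHit(template_id, Interval(seq_id, s, s + length), 1.0, 1.0) for s in starts
    ]


def hits_from_gaps(gaps, length=30, start=1000, **kw):
    starts, pos = [start], start
    for g in gaps:
        pos += length + g
        starts.append(pos)
    return mk_hits(starts, length, **kw)


@pytest.mark.parametrize(
    "gaps,expected_sizes",
    [
        ([35, 40, 38], [4]),
        ([35, 300, 38], [2, 2]),  # 300 > 120 splits the chain
        ([5], [1, 1]),  # 5 < 10 cannot be a spacer
        ([10, 120], [3]),  # boundary gaps are inclusive
    ],
)
def test_assemble_chaining(gaps, expected_sizes):
    arrays = assemble_arrays(hits_from_gaps(gaps))
    assert [a.n_dr for a in arrays] == expected_sizes
    for a in arrays:
        assert a.n_spacer == a.n_dr - 1


def test_assemble_rejects_overlapping_hits():
    with pytest.raises(ValueError):
        assemble_arrays(mk_hits([1000, 1010]))


def build_genome_with_split_array(rng):
    """Array of 5 copies whose middle copy is 70% identity: naive mapping
    sees two 2-copy arrays with a 100-bp gap containing the degenerate DR."""
    unit = random_seq(rng, 30)
    degen = list(unit)
    for p in rng.choice(30, size=9, replace=False):
        degen[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[degen[p]]
    sp = [random_seq(rng, 35) for _ in range(4)]
    block = unit + sp[0] + unit + sp[1] + "".join(degen) + sp[2] + unit + sp[3] + unit
    lead = random_seq(rng, 500)
    genome = GenomeRecord("g", lead + block + random_seq(rng, 500))
    s0 = 500
    starts = [s0, s0 + 65, s0 + 130, s0 + 195, s0 + 260]
    return genome, unit, starts


def test_merge_same_template_rescues_gap_copy(rng):
    genome, unit, starts = build_genome_with_split_array(rng)
    a = CRISPRArray("?", "g", "T1", unit, mk_hits(starts[:2]))
    b = CRISPRArray("?", "g", "T1", unit, mk_hits(starts[3:]))
    merged = merge_same_template([a, b], genome)
    assert len(merged) == 1
    assert merged[0].n_dr == 5
    assert [h.location.start for h in merged[0].dr_copies] == starts


def test_merge_requires_same_template(rng):
    genome, unit, starts = build_genome_with_split_array(rng)
    a = CRISPRArray("?", "g", "T1", unit, mk_hits(starts[:2], template_id="T1"))
    b = CRISPRArray("?", "g", "T2", unit, mk_hits(starts[3:], template_id="T2"))
    assert len(merge_same_template([a, b], genome)) == 2


def test_merge_respects_distance_bound(rng):
    genome = GenomeRecord("g", random_seq(rng, 12_000))
    unit = random_seq(rng, 30)
    a = CRISPRArray("?", "g", "T1", unit, mk_hits([1000, 1065]))
    b = CRISPRArray("?", "g", "T1", unit, mk_hits([7000, 7065]))  # 5 kb apart
    assert len(merge_same_template([a, b], genome)) == 2


def test_spacer_filter_keeps_random_discards_identical(rng):
    unit = random_seq(rng, 30)
    spacer = random_seq(rng, 35)
    # identical spacers
    block = unit + spacer + unit + spacer + unit + spacer + unit
    genome = GenomeRecord("g", random_seq(rng, 200) + block + random_seq(rng, 200))
    arr = CRISPRArray("?", "g", "T1", unit, mk_hits([200 + i * 65 for i in range(4)]))
    keep, reason = spacer_false_positive_filter(arr, genome)
    assert not keep and "similarity" in reason
    # independent random spacers
    genome2, starts = plant_exact(rng, 3000, unit, 4)
    arr2 = CRISPRArray("?", "g", "T1", unit, mk_hits(starts))
    keep2, _ = spacer_false_positive_filter(arr2, genome2)
    assert keep2


def test_spacer_filter_not_applicable_below_two_spacers(rng):
    genome, starts = plant_exact(rng, 2000, random_seq(rng, 30), 2)
    arr = CRISPRArray("?", "g", "T1", "", mk_hits(starts))
    keep, reason = spacer_false_positive_filter(arr, genome)
    assert keep and "not applicable" in reason


def test_extend_termini_recovers_divergent_terminals(rng):
    from drscan import PlantSpec, generate_genome
    from drscan.simulate import apply_terminal_divergence
    from drscan.mapping import map_template

    spec = PlantSpec(genome_len=40_000, n_arrays=1, dr_copies_range=(6, 6),
                     dr_divergence=0.0, seed=9)
    genome, truth = generate_genome(spec)
    genome = apply_terminal_divergence(genome, truth, "G1", 0.2, seed=9)
    gold = truth.arrays[0]
    unit = truth.planted_sequences[0][1]
    # interior anchors only (terminals are 20% diverged)
    interior = [
        DRHit("T1", iv, 1.0, 1.0) for iv in gold.dr_intervals[1:-1]
    ]
    arr = CRISPRArray("?", genome.seq_id, "T1", unit, interior)
    out = extend_termini(arr, genome)
    assert out.n_dr == 6
    got = [(h.location.start, h.location.end) for h in out.dr_copies]
    assert got == [(iv.start, iv.end) for iv in gold.dr_intervals]
    # idempotence on an already-maximal array
    again = extend_termini(out, genome)
    assert again.n_dr == 6


def test_extend_termini_rejects_short_spacer_at_default(rng):
    unit = random_seq(rng, 30)
    sp = [random_seq(rng, 35) for _ in range(2)]
    short = random_seq(rng, 7)
    block = unit + sp[0] + unit + sp[1] + unit + short + unit
    genome = GenomeRecord("g", random_seq(rng, 400) + block + random_seq(rng, 400))
    starts = [400, 465, 530]
    arr = CRISPRArray("?", "g", "T1", unit, mk_hits(starts))
    assert extend_termini(arr, genome).n_dr == 3  # 7 < 10 rejected
    relaxed = ArrayConfig(spacer_min_len=5)
    arr2 = CRISPRArray("?", "g", "T1", unit, mk_hits(starts))
    out = extend_termini(arr2, genome, relaxed)
    assert out.n_dr == 4
    assert out.dr_copies[-1].location.start == 530 + 30 + 7


def test_finalize_absorbs_overlapping_and_orders_ids(rng):
    unit = random_seq(rng, 30)
    genome, starts = plant_exact(rng, 6000, unit, 10)
    big = CRISPRArray("?", "g", "T1", unit, mk_hits(starts))
    small = CRISPRArray("?", "g", "T2", unit, mk_hits(starts[3:6], template_id="T2"))
    out = finalize([small, big], genome)
    assert len(out) == 1
    assert out[0].n_dr == 10 and out[0].array_id == "CRISPR1"


def test_finalize_drops_out_of_band_consensus(rng):
    unit60 = random_seq(rng, 60)
    genome, starts = plant_exact(rng, 6000, unit60, 4)
    arr = CRISPRArray("?", "g", "T1", unit60, mk_hits(starts, length=60))
    assert finalize([arr], genome) == []


def test_finalize_drops_under_min_copies(rng):
    unit = random_seq(rng, 30)
    genome, starts = plant_exact(rng, 3000, unit, 2)
    arr = CRISPRArray("?", "g", "T1", unit, mk_hits(starts))
    assert finalize([arr], genome) == []
    assert len(finalize([arr], genome, ArrayConfig(min_dr_copies=2))) == 1


def test_finalize_disjoint_arrays_kept_and_invariants(rng):
    unit1, unit2 = random_seq(rng, 30), random_seq(rng, 34)
    sp = 40
    rng2 = np.random.default_rng(999)
    g1, starts1 = plant_exact(rng, 20_000, unit1, 4)
    seq = g1.sequence
    # plant the second array far away
    block = unit2
    starts2 = []
    pos = 15_000
    for i in range(5):
        starts2.append(pos)
        seq = seq[:pos] + unit2 + seq[pos + 34 :]
        pos += 34 + sp
    genome = GenomeRecord("g", seq)
    a = CRISPRArray("?", "g", "T1", unit1, mk_hits(starts1, 30))
    b = CRISPRArray("?", "g", "T2", unit2, mk_hits(starts2, 34, template_id="T2"))
    out = finalize([b, a], genome)
    assert [x.array_id for x in out] == ["CRISPR1", "CRISPR2"]
    for arr in out:
        # alternation: spacers exactly tile inter-DR gaps, all inside bounds
        assert arr.n_spacer == arr.n_dr - 1
        for prev, nxt, s in zip(arr.dr_copies, arr.dr_copies[1:], arr.spacers):
            assert s.start == prev.location.end and s.end == nxt.location.start
        assert 0 <= arr.span.start < arr.span.end <= genome.length
        assert 23 <= len(arr.consensus_dr) <= 55
    # no overlap between final arrays
    assert out[0].span.end <= out[1].span.start


def test_pipeline_deterministic_outputs(tmp_path, clean_planted):
    from drscan import RunConfig, run_pipeline, write_fasta

    genome, _ = clean_planted
    fasta = write_fasta([genome], tmp_path / "g.fasta")
    outs = []
    for name in ("a", "b"):
        _, paths = run_pipeline(fasta, RunConfig(out_prefix=str(tmp_path / name)))
        outs.append({k: p.read_text() for k, p in paths.items()})
    assert outs[0] == outs[1]
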