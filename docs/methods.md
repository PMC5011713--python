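# Methods

## Problem and model

A CRISPR array is an alternation of near-identical direct repeats (DRs) and
unique spacers. Empirically (from curated prokaryotic annotations) DRs span
23–55 bp with a mean near 31 bp, and spacers average ~36 bp but range much
wider; for detection the spacer band is taken as 10–120 bp. `drscan` treats
detection as a repeat problem with three structural constraints: the repeat
unit length band, the gap (spacer) length band, and the requirement that
spacers be mutually dissimilar (each spacer is an independent acquisition;
a "CRISPR" whose spacers resemble one another is a tandem repeat in
disguise).

Coordinates are 0-based half-open internally; every emitted file is 1-based
inclusive. IUPAC ambiguity codes are normalized to N, and N never matches
anything in any comparison, so assembly gaps cannot fabricate identity.

## Template discovery

Exact `seed_k`-mers (default 15 = the minimum template length) occurring at
least twice are grouped; groups are extended one column at a time in each
direction. Per column the majority base among the group's copies becomes
the consensus and the column scores `2·maxcount − n − 1`; extension stops
when the cumulative score falls 8 below its running maximum (X-drop) and
the extent is trimmed back to that maximum. The constant −1 makes the
expected score negative on random sequence even for 3–4 copies, where a
plain match-minus-mismatch score against a majority consensus drifts
upward by chance. Copies whose full-template identity to the consensus is
below 0.8 are dropped, mirroring the 0.8 identity floor used in mapping.

Seeding from pairs (rather than requiring three exact seed occurrences)
matters for small diverged arrays: with i.i.d. per-copy divergence d, two
copies share an unmutated k-mer window far more often than three do. Every
extended consensus is then *verified* genome-wide in two rounds: a loose
round (identity ≥ 0.75, full length) collects candidate copies; the
consensus is rebuilt as their column majority and re-trimmed (weak-column
trim, pivot 0.7 — this removes flank bases the two seed copies happened to
share); a final round at ≥ 0.8 identity fixes the copy set. The two rounds
matter because a pair-derived consensus carries roughly the per-copy
divergence in errors, which would leave true copies straddling the 0.8
floor. When the loose round finds too few copies for a candidate of
≥ 20 bp, it is retried with a smaller (7-mer) seed index — highly diverged
copies may carry no exact 9-mer. Only templates with at least `min_copies`
(default 3) verified copies are emitted, restoring the three-copy evidence
requirement at the template level. Boundary-shifted variants of one repeat
are collapsed by copy-set occupancy, keeping the variant with the highest
identity × length (so a short exact fragment of a diverged repeat cannot
shadow the full-length template).

Terminal trimming uses a cumulative rule: from each end, the running sum of
(column agreement − pivot) is tracked and the end is cut at its minimum.
A single flank column that agrees by chance therefore cannot shield a weak
run. Discovery trims at pivot 0.85 because X-drop over-extension is
*enriched* for chance-agreeing columns (the extension only continued
because they agreed); the verified-copy re-trim uses 0.7 because verified
copies are located independently and their flank columns are unbiased.

Low-complexity templates are removed only when the normalized Shannon
entropy of their base composition falls below 1 − 0.9 = 0.1 — a deliberately
permissive cutoff so genuinely low-complexity DRs survive — and templates
that are themselves tandem repetitions of a ≤ 6 bp unit (periodic match
fraction ≥ 0.8) are removed as microsatellites.

## Similar ratio and clustering

The *similar ratio* of two sequences is the number of identical aligned
pairs under optimal global alignment (match +1, mismatch −1, gap −2)
divided by the longer length; among co-optimal alignments the
identity-maximal one defines the count, so the statistic is well defined.
The dual (score, identities) dynamic program is JIT-compiled with numba; a
pure-Python fallback keeps the package importable without it. Max-length
normalization is the strictest of the plausible choices; with the 0.8
threshold it merges a 30-bp DR carrying up to 6 differences.

Templates with ratio > 0.8 cluster by single linkage ("highly similar DRs
are one kind of template"), and the representative is the medoid member —
an observed sequence, not a synthetic consensus — with ties broken by copy
count, then leftmost genomic start. Cluster IDs follow genomic order, so
clustering is invariant to input permutation.

## Mapping and rescue

Representatives are mapped on both strands by exact 9-mer seeding against a
sorted k-mer index of the record, followed by direct evaluation of each
implied placement: full-length identity first, then the maximal-scoring
(matches − mismatches) prefix or suffix for truncated copies. The seed size
9 keeps a 30-bp copy with three substitutions detectable with high
probability; the alignment model is substitution-only, which matches how
DR copies actually degenerate (and the synthetic generator); copies with
internal indels are recovered, if at all, by the window rescue below.
Partial (truncated) placements must additionally be significant against a
genome-wide binomial null (match probability 0.25, Bonferroni over both
strands of the record, α = 0.01), because a short exact prefix alone is
ambiguous on megabase scales. Hits of one template may overlap by at most
half the template length; best-identity-first selection resolves the rest.

Window rescue re-scans bounded regions — the two flanks of an array and
inter-hit gaps long enough to hold a DR plus two spacers — by sliding the
template across every offset, at permissive thresholds (identity ≥ 0.6,
coverage ≥ 0.4). A copy missed inside an array does not always split the
chain (two consecutive spacers can masquerade as one legal spacer), so the
internal gaps of every assembled array are re-scanned too, with the
inserted copy required to leave two in-band spacers. Because the windows
are anchored by an existing array, the multiple-testing burden is the
window's offsets (×2 for the prefix/suffix anchor choice), and candidates
must clear a binomial tail test at α = 0.001. The α values are design
constants chosen for ~10³ trials per window so that a random flank
essentially never yields a copy, while a 70%-identity degenerate DR or a
60%-length truncated terminal passes by many orders of magnitude.

## Assembly, filtering, finalization

Hits chain greedily while gaps stay within the spacer band; a gap outside
the band splits the chain. Same-template neighbouring arrays merge when
separated by at most one DR plus two maximal spacers, after the gap is
re-scanned for the degenerate copy that caused the split; each array's own
internal gaps are re-scanned the same way (a missed copy does not always
split the chain — two consecutive spacers can masquerade as one legal
spacer). The spacer false-positive rule discards an array when the *mean*
pairwise similar ratio of its spacers exceeds 0.5; the mean (rather than
any-pair) tolerates the occasional legitimately duplicated spacer observed
in real arrays. Terminal extension repeats window rescue on the flanks and
accepts a copy only if the implied spacer lies in the band.

Finalization pools all candidates. The consensus of each candidate is
first recomputed by column majority over its full-length copies with
strict terminal trimming (pivot 0.85, falling back to 0.7 if that would
cut below the 23 bp minimum); a consensus still longer than 55 bp sheds
weakly supported (< 0.8 agreement) terminal columns, while one shorter
than 23 bp is grown back outward while the adjacent genome column is
supported at ≥ 0.7 across the copies — so boundary noise cannot disqualify
an array, while a genuinely out-of-band repeat (strongly supported long
columns, or flanks that never agree) is still dropped by the 23–55 bp
band. The band filter runs *before* overlap resolution on purpose: an
array assembled from a short fragment of the true DR must not absorb the
viable full-length array on the same locus and then be discarded. Among
band-valid candidates, overlapping arrays are combined with the
copy-richer one absorbing (ties by mean identity, then leftmost), merging
is re-applied across the pool, and arrays with fewer than 3 DR copies are
dropped. Array IDs follow genomic order and outputs are byte-stable.

Arrays are built per strand and never mix strands; DR and spacer sequences
are reported in the array's strand orientation.

## Evaluation statistics

NumDR counts predicted DR copies whose midpoint falls within a known
array's span extended by a slack (default 200 bp ≈ one DR plus one maximal
spacer, making "in the location of" explicit and tunable); each predicted
copy counts once. rDR = NumDR / known copy count and may exceed 1; rCRISPR
is the arithmetic mean of rDR over the known arrays of a genome. The gold
standard is a plain TSV (`gold_id, seq_id, dr_start, dr_end`, 1-based
inclusive, one row per DR copy).

## Synthetic genomes

The generator plants arrays in i.i.d. background at a configurable GC
content, with ≥ 500 bp clearance around every planted block. Defaults
follow the empirical bands: DR length uniform in 23–55 bp, 3–30 copies,
spacers uniform in 20–60 bp. Per-copy divergence mutates exactly
`round(d·L)` positions, so truth-vs-genome checks are exact. Spacers are
re-sampled until all pairwise similar ratios are ≤ 0.4 — safely below the
0.5 false-positive threshold — so a planted array is detectable in
principle and failures indict the detector, not the fixture. Corruption
operators reproduce known annotator failure modes: `truncate_terminal_dr`
(outer 40% of a terminal copy removed), `degenerate_internal_dr` (an
internal copy mutated to ~70% identity, the classic array-splitting case),
`short_spacer` (a 7-bp terminal spacer), and `tandem_decoy` (a 35-mer
repeated back-to-back ten times, absent from truth).

What the generator does *not* emulate: real genomic repeat families (IS
elements, rRNA operons), leader sequences and Cas genes, copy-number or
length autocorrelation within arrays, and indel-type DR degeneration.
Passing the synthetic suite therefore demonstrates the structural logic of
the detector under substitution noise, not performance on real genomes.

## Problem sizes and acceptance checks

The acceptance suite and `scripts/acceptance.py` use 100 replicates of
1 Mb genomes with 3 arrays each (4–30 copies; per-replicate divergence
drawn uniformly from [0, 0.10], covering the "up to 10%" condition) for
recovery; 100 negative-control genomes of 50 and 20 kb; 50 genomes of
2–5 kb for the discovery-vs-brute-force oracle; and 150 random pairs of
≤ 20 bp sequences for the alignment oracle. One 1 Mb genome takes about
2–3 s to simulate and detect on one CPU. The recovery bar is strict: a
replicate counts only if *every* planted array has rDR exactly 1.0 — one
missed or one spuriously added DR copy fails the replicate.

## Known limitations

- Substitution-only matching: DR copies with internal indels may be missed
  or reported with shifted boundaries.
- An array none of whose copy pairs share a single unmutated seed-length
  k-mer is undetectable by construction (observed roughly once per hundred
  simulated genomes at the divergence extreme); lowering `seed_k` trades
  this away for substantially more chance seed groups.
- Cross-contig partial arrays are not joined; an array truncated at a
  record boundary is reported only as far as its on-record copies.
- Arrays with only 2 copies are invisible at defaults (`min_dr_copies` and
  discovery `min_copies` must both be lowered to 2).
- The 15 bp minimum template length means DRs shorter than 15 bp (below the
  23 bp empirical minimum anyway) are undetectable by construction.
- At 4 copies and ~10% divergence near the DR length extremes, boundary
  trimming is working at its statistical limit; recovery remains above the
  95% replicate bar but individual boundaries can be off by 1–2 bp.
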