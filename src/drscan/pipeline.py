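"""End-to-end orchestration: FASTA in, annotated CRISPR arrays out.

Stage order per genome record: template discovery -> complexity/tandem
filtering -> template clustering -> genome mapping of each representative
-> per-strand array assembly -> same-template merging -> spacer
false-positive filter -> terminal extension -> pooled finalization ->
table/GFF3 output.  Zero detected arrays is a valid outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .arrays import (
    ArrayConfig,
    CRISPRArray,
    assemble_arrays,
    extend_termini,
    finalize,
    merge_same_template,
    rescue_internal,
    spacer_false_positive_filter,
)
from .clustering import DR_SIMILARITY_THRESHOLD, cluster_templates
from .discovery import DiscoveryConfig, filter_templates, find_repeat_templates
from .io import GenomeRecord, read_fasta, write_annotation_tables, write_gff3
from .mapping import DRHit, KmerIndex, MappingConfig, map_template

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Aggregated configuration; every field has a default, so a genome
    FASTA is the only required input."""

    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    arrays: ArrayConfig = field(default_factory=ArrayConfig)
    dr_similarity_threshold: float = DR_SIMILARITY_THRESHOLD
    slack: int = 200
    out_prefix: str = "drscan_out"
    log_level: str = "INFO"


def _resolve_overlaps(hits: list[DRHit]) -> list[DRHit]:
    """Strictly non-overlapping subset, best identity first (assembly
    requires disjoint hits)."""
    chosen: list[DRHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, -h.coverage, h.location.start)):
        if all(not h.location.overlaps(c.location) for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.location.start)
    return chosen


def detect_record(genome: GenomeRecord, config: RunConfig | None = None) -> list[CRISPRArray]:
    """Run all detection stages on one genome record."""
    config = config or RunConfig()
    index = KmerIndex(genome)
    templates = find_repeat_templates(genome, config.discovery, index)
    kept = filter_templates(templates, config.discovery)
    logger.info(
        "%s: %d templates discovered, %d after filtering", genome.seq_id, len(templates), len(kept)
    )
    if not kept:
        return []
    clusters = cluster_templates(kept, config.dr_similarity_threshold)
    logger.info("%s: %d template clusters", genome.seq_id, len(clusters))

    candidates: list[CRISPRArray] = []
    for cluster in clusters:
        rep = cluster.representative
        hits = map_template(genome, rep, config.mapping, index, cluster.cluster_id)
        for strand in "+-":
            strand_hits = _resolve_overlaps(
                [h for h in hits if h.location.strand == strand]
            )
            if not strand_hits:
                continue
            arrays = assemble_arrays(strand_hits, config.arrays, rep, genome.seq_id)
            arrays = merge_same_template(arrays, genome, config.arrays, config.mapping)
            arrays = [
                rescue_internal(a, genome, config.arrays, config.mapping)
                if a.n_dr >= 2
                else a
                for a in arrays
            ]
            for arr in arrays:
                keep, reason = spacer_false_positive_filter(arr, genome, config.arrays)
                if not keep:
                    logger.info("%s: discarded candidate (%s)", genome.seq_id, reason)
                    continue
                # a single isolated hit carries no spacer evidence; it may
                # still merge later but is not worth flank scans
                if arr.n_dr >= 2:
                    arr = extend_termini(arr, genome, config.arrays, config.mapping)
                candidates.append(arr)
    logger.info("%s: %d candidate arrays before finalization", genome.seq_id, len(candidates))
    final = finalize(candidates, genome, config.arrays, config.mapping)
    logger.info("%s: %d final arrays", genome.seq_id, len(final))
    return final


def detect(
    genomes: list[GenomeRecord], config: RunConfig | None = None
) -> list[CRISPRArray]:
    """Detect arrays on every record; array IDs are unique across records."""
    config = config or RunConfig()
    out: list[CRISPRArray] = []
    for genome in genomes:
        out.extend(detect_record(genome, config))
    out.sort(key=lambda a: (a.seq_id, a.span.start))
    for i, a in enumerate(out, start=1):
        a.array_id = f"CRISPR{i}"
    return out


def run_pipeline(
    fasta: str | Path, config: RunConfig | None = None
) -> tuple[list[CRISPRArray], dict[str, Path]]:
    """Detect arrays in a FASTA file and write the annotation outputs.

    Returns the arrays and the paths of the three tab-delimited tables plus
    the GFF3 file.
    """
    config = config or RunConfig()
    genomes = read_fasta(fasta)
    arrays = detect(genomes, config)
    p_arr, p_dr, p_sp = write_annotation_tables(arrays, config.out_prefix)
    gff = write_gff3(arrays, Path(config.out_prefix).with_suffix(".gff3"))
    return arrays, {"arrays": p_arr, "drs": p_dr, "spacers": p_sp, "gff3": gff}
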