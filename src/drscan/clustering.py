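"""Grouping of near-identical repeat templates into one DR class.

A de-novo screen frequently reports neighbouring DR copies of one array as
several distinct templates; single-linkage clustering on the pairwise
"similar ratio" (> 0.8) collapses them, and the medoid member becomes the
class representative that is mapped back onto the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import global_identity_count
from .discovery import RepeatTemplate

DR_SIMILARITY_THRESHOLD = 0.8


def similarity_ratio(a: str, b: str) -> float:
    """Identical aligned pairs under optimal global alignment, divided by
    max(len(a), len(b)).  Symmetric; N matches nothing."""
    if not a or not b:
        raise ValueError("similarity_ratio requires non-empty sequences")
    return global_identity_count(a, b) / max(len(a), len(b))


@dataclass
class TemplateCluster:
    cluster_id: str
    members: list[RepeatTemplate]
    representative: str


def _min_start(t: RepeatTemplate) -> int:
    return min(c.start for c in t.copies) if t.copies else 0


def select_representative(members: list[RepeatTemplate]) -> str:
    """Medoid consensus: maximal similarity sum to the other members; ties
    broken by larger copy count, then leftmost genomic start."""
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0].consensus
    best = None
    for t in members:
        s = sum(similarity_ratio(t.consensus, u.consensus) for u in members if u is not t)
        key = (s, t.copy_count, -_min_start(t))
        if best is None or key > best[0]:
            best = (key, t)
    return best[1].consensus


def cluster_templates(
    templates: list[RepeatTemplate], threshold: float = DR_SIMILARITY_THRESHOLD
) -> list[TemplateCluster]:
    """Single-linkage clusters over the graph of pairs with similarity
    strictly above ``threshold``; cluster IDs follow genomic order of the
    smallest member start, so the output is permutation-invariant."""
    n = len(templates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if similarity_ratio(templates[i].consensus, templates[j].consensus) > threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[RepeatTemplate]] = {}
    for i, t in enumerate(templates):
        groups.setdefault(find(i), []).append(t)

    ordered = sorted(groups.values(), key=lambda ms: min(_min_start(t) for t in ms))
    clusters = []
    for ci, members in enumerate(ordered, start=1):
        members = sorted(members, key=_min_start)
        clusters.append(TemplateCluster(f"C{ci}", members, select_representative(members)))
    return clusters
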