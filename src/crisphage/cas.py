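"""Rule-based CRISPR-Cas subtype classification and defense-budget accounting.

Subtypes are called from the set of cas gene labels present in a genome,
using explicit gene-content rules for the five subtypes observed in
Saccharibacteria, Gracilibacteria and Absconditabacteria: II-A, II-C1, V-A,
III-A and III-B.  A system is only considered complete when the genome also
carries a high-confidence CRISPR array.  The budget operation measures how
much of a genome is devoted to CRISPR-Cas defense (cas genes plus arrays,
as an interval union).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

from .orfs import interval_union_length

__all__ = [
    "CasGene",
    "CasSystemCall",
    "classify_system",
    "crispr_budget",
    "KNOWN_LABELS",
    "SUBTYPE_RULES",
]

KNOWN_LABELS: FrozenSet[str] = frozenset(
    {
        "cas9", "csn2", "cas1", "cas2", "cas4", "cpf1",
        "cas10", "cas7", "cas5", "csm2", "cmr5", "other",
    }
)

# (subtype, required labels, forbidden labels) in application order
SUBTYPE_RULES: Tuple[Tuple[str, FrozenSet[str], FrozenSet[str]], ...] = (
    ("II-A", frozenset({"cas9", "csn2", "cas1", "cas2"}), frozenset()),
    ("II-C1", frozenset({"cas9", "cas1", "cas2"}), frozenset({"csn2"})),
    ("V-A", frozenset({"cpf1", "cas1", "cas4", "cas2"}), frozenset()),
    ("III-A", frozenset({"cas10", "cas7", "cas5", "csm2"}), frozenset()),
    ("III-B", frozenset({"cas10", "cas7", "cas5", "cmr5"}), frozenset()),
)


@dataclass(frozen=True)
class CasGene:
    """One annotated cas gene interval (0-based half-open, forward coords)."""

    genome_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    label: str


@dataclass(frozen=True)
class CasSystemCall:
    """The subtype call(s) for one genome's pooled cas gene content."""

    genome_id: str
    subtypes: Tuple[str, ...]  # ("incomplete",) when no rule fires
    genes_matched: FrozenSet[str]
    has_high_evidence_array: bool


def classify_system(
    labels: Iterable[str],
    has_high_evidence_array: bool,
) -> Tuple[str, ...]:
    """Call CRISPR-Cas subtype(s) from a genome's cas gene labels.

    Rules, applied in order over the pooled label set:

    - II-A:  cas9 + csn2 + cas1 + cas2
    - II-C1: cas9 + cas1 + cas2, without csn2
    - V-A:   cpf1 + cas1 + cas4 + cas2
    - III-A: cas10 + cas7 + cas5 + csm2
    - III-B: cas10 + cas7 + cas5 + cmr5

    All satisfied subtypes are returned (genomes with several cas loci
    exist; III-A and III-B co-fire when both csm2 and cmr5 are present).
    Without a high-confidence CRISPR array, or when no rule fires, the call
    is ``("incomplete",)``.  Unknown labels trigger a warning and are
    ignored.
    """
    normalized = set()
    for raw in labels:
        label = str(raw).strip().lower()
        if label not in KNOWN_LABELS:
            warnings.warn(f"ignoring unknown cas gene label: {raw!r}")
            continue
        normalized.add(label)
    if not has_high_evidence_array:
        return ("incomplete",)
    calls = tuple(
        subtype
        for subtype, required, forbidden in SUBTYPE_RULES
        if required <= normalized and not (forbidden & normalized)
    )
    return calls if calls else ("incomplete",)


def crispr_budget(
    genome_length: int,
    cas_intervals: Sequence[Tuple[int, int]],
    array_intervals: Sequence[Tuple[int, int]],
) -> Tuple[int, float]:
    """Base pairs (interval union) and genome fraction devoted to defense.

    Overlapping cas gene and array intervals are counted once.  Returns
    (total_bp, fraction of genome).
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    intervals = list(cas_intervals) + list(array_intervals)
    for s, e in intervals:
        if s < 0 or e > genome_length or e < s:
            raise IndexError(
                f"interval [{s}, {e}) outside genome of length {genome_length}"
            )
    total = interval_union_length(intervals)
    return total, total / genome_length


def pool_labels(genes: Sequence[CasGene], per_scaffold: bool = False) -> Dict[str, List[str]]:
    """Group cas gene labels per genome (default) or per scaffold.

    Genome-level pooling mirrors gene-content rules phrased as "encoded
    within the same genome"; per-scaffold mode is stricter for fragmented
    assemblies.
    """
    pooled: Dict[str, List[str]] = {}
    for g in genes:
        key = f"{g.genome_id}:{g.seq_id}" if per_scaffold else g.genome_id
        pooled.setdefault(key, []).append(g.label)
    return pooled
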