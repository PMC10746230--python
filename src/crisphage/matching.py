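"""Spacer-to-protospacer matching and phage-host linking.

Matching uses an exact, ungapped Hamming model mirroring short-read BLASTn
thresholds: a spacer hits a target window when at least ``min_coverage`` of
the spacer aligns with at most ``max_mismatch`` substitutions.  Coverage
below 1.0 is realised by truncating the spacer at either end (as alignment
ends erode), never by interior gaps.  A spacer-protospacer hit ties a phage
to the bacterial lineage whose CRISPR array stores the spacer; phages hit by
spacers of both an SGA lineage (Saccharibacteria / Gracilibacteria /
Absconditabacteria) and a non-SGA lineage are flagged co-targeted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .arrays import SpacerDb
from .genetic_codes import reverse_complement

__all__ = [
    "SpacerHit",
    "HostLink",
    "match_spacer",
    "link_hosts",
    "find_cotargeted",
    "shared_spacers",
    "SGA_GROUPS",
    "DEFAULT_MIN_COVERAGE",
    "DEFAULT_MAX_MISMATCH",
    "MIN_SPACER_LEN",
]

DEFAULT_MIN_COVERAGE = 0.95
DEFAULT_MAX_MISMATCH = 1
MIN_SPACER_LEN = 15  # hard floor; spurious-match guard for short spacers

SGA_GROUPS: FrozenSet[str] = frozenset(
    {"saccharibacteria", "gracilibacteria", "absconditabacteria"}
)


@dataclass(frozen=True)
class SpacerHit:
    """One ungapped spacer-target match.

    Coordinates are 0-based half-open on the target's forward strand; strand
    ``'-'`` means the spacer matches the reverse strand.  ``coverage`` is
    matched_len over full spacer length.
    """

    spacer_id: str
    target_id: str
    start: int
    end: int
    strand: str
    matched_len: int
    mismatches: int
    coverage: float


@dataclass(frozen=True)
class HostLink:
    """All spacer support tying one phage (target) to candidate host lineages."""

    target_id: str
    hits: Tuple[SpacerHit, ...]
    host_groups: Tuple[str, ...]  # one per hit, parallel to `hits`

    @property
    def group_set(self) -> FrozenSet[str]:
        return frozenset(g.lower() for g in self.host_groups)


def _mismatch_profile(target_b: np.ndarray, pattern: bytes) -> np.ndarray:
    """Hamming distance of `pattern` against every target window."""
    m = len(pattern)
    nw = len(target_b) - m + 1
    if nw <= 0:
        return np.empty(0, dtype=np.int32)
    p = np.frombuffer(pattern, dtype=np.uint8)
    counts = np.zeros(nw, dtype=np.int32)
    for j in range(m):
        counts += target_b[j : j + nw] != p[j]
    return counts


def match_spacer(
    spacer: str,
    target: str,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    spacer_id: str = "spacer",
    target_id: str = "target",
) -> List[SpacerHit]:
    """Find all ungapped matches of a spacer in a target, on both strands.

    Every window length from ``ceil(min_coverage * L)`` to the full spacer
    length ``L`` is tried, anchored at either spacer end (terminal
    truncation only).  Overlapping hits on one strand are merged, keeping
    minimal mismatches, then maximal matched length, then the leftmost.
    """
    sp = spacer.upper()
    tg = target.upper()
    L = len(sp)
    if L < MIN_SPACER_LEN:
        raise ValueError(
            f"spacer shorter than {MIN_SPACER_LEN} nt ({L} nt): too prone to "
            "spurious matches"
        )
    lmin = math.ceil(min_coverage * L)
    target_b = np.frombuffer(tg.encode("ascii"), dtype=np.uint8)

    raw: List[SpacerHit] = []
    for strand, oriented in (("+", sp), ("-", reverse_complement(sp))):
        windows = set()
        for lp in range(lmin, L + 1):
            windows.add(oriented[:lp])  # one spacer end
            windows.add(oriented[L - lp :])  # the other end
        for w in sorted(windows, key=len, reverse=True):
            counts = _mismatch_profile(target_b, w.encode("ascii"))
            for i in np.nonzero(counts <= max_mismatch)[0]:
                raw.append(
                    SpacerHit(
                        spacer_id=spacer_id,
                        target_id=target_id,
                        start=int(i),
                        end=int(i) + len(w),
                        strand=strand,
                        matched_len=len(w),
                        mismatches=int(counts[i]),
                        coverage=len(w) / L,
                    )
                )
    return _merge_overlapping(raw)


def _merge_overlapping(hits: List[SpacerHit]) -> List[SpacerHit]:
    """Collapse clusters of overlapping same-strand hits to their best member."""
    merged: List[SpacerHit] = []
    for strand in ("+", "-"):
        cluster: List[SpacerHit] = []
        for h in sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: (h.start, h.end),
        ):
            if cluster and h.start < max(c.end for c in cluster):
                cluster.append(h)
            else:
                if cluster:
                    merged.append(_best(cluster))
                cluster = [h]
        if cluster:
            merged.append(_best(cluster))
    merged.sort(key=lambda h: (h.start, h.end, h.strand))
    return merged


def _best(cluster: List[SpacerHit]) -> SpacerHit:
    return min(cluster, key=lambda h: (h.mismatches, -h.matched_len, h.start))


def link_hosts(
    spacer_db: SpacerDb,
    targets: Mapping[str, str],
    host_groups: Mapping[str, str],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> List[HostLink]:
    """Match every database spacer against every target and aggregate.

    ``host_groups`` maps each spacer's source genome id to its lineage name
    (e.g. Gracilibacteria, Firmicutes).  Returns one :class:`HostLink` per
    target with at least one hit, ordered by target id.
    """
    links: List[HostLink] = []
    for target_id in sorted(targets):
        tseq = targets[target_id]
        hits: List[SpacerHit] = []
        groups: List[str] = []
        for rec in spacer_db.entries:
            try:
                group = host_groups[rec.source_id]
            except KeyError:
                raise KeyError(
                    f"no host group for spacer source {rec.source_id!r}"
                ) from None
            for h in match_spacer(
                rec.sequence,
                tseq,
                min_coverage=min_coverage,
                max_mismatch=max_mismatch,
                spacer_id=rec.spacer_id,
                target_id=target_id,
            ):
                hits.append(h)
                groups.append(group)
        if hits:
            links.append(
                HostLink(
                    target_id=target_id,
                    hits=tuple(hits),
                    host_groups=tuple(groups),
                )
            )
    return links


def find_cotargeted(
    links: Sequence[HostLink],
    sga_groups: Iterable[str] = SGA_GROUPS,
) -> List[Tuple[str, FrozenSet[str]]]:
    """Targets hit by spacers of both an SGA and a non-SGA lineage.

    Returns (target_id, supporting group set) pairs in target-id order.
    """
    sga = frozenset(g.lower() for g in sga_groups)
    out: List[Tuple[str, FrozenSet[str]]] = []
    for link in links:
        groups = link.group_set
        if len(groups) >= 2 and (groups & sga) and (groups - sga):
            out.append((link.target_id, groups))
    return out


def shared_spacers(
    inventory_a: Iterable[str],
    inventory_b: Iterable[str],
) -> List[Tuple[str, str]]:
    """Spacer sequences identical over their full length in both inventories.

    Both orientations are checked (100% identity, 100% coverage).  Returns
    (sequence as seen in inventory a, orientation) pairs, orientation ``'+'``
    for direct identity and ``'-'`` when only the reverse complement occurs
    in inventory b.  An empty result supports ruling out horizontal spacer
    transfer between the two genomes.
    """
    set_b = {s.upper() for s in inventory_b}
    out: List[Tuple[str, str]] = []
    for s in sorted({s.upper() for s in inventory_a}):
        if s in set_b:
            out.append((s, "+"))
        elif reverse_complement(s) in set_b:
            out.append((s, "-"))
    return out
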