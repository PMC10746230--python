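"""Six-frame ORF calling, coding density and the dual-code classifier.

The central diagnostic of this package is the coding-density delta: a genome
written in genetic code 25 (TGA = glycine) is riddled with in-frame TGA codons,
so calling ORFs under the standard code 11 shatters its genes and the code-11
coding density collapses, while calling under code 25 recovers them.  Genomes
compatible with the standard code show near-identical densities under both
codes.  The difference d25 - d11, in percentage points, therefore classifies a
phage genome's genetic code.

The ORF model is deliberately simple and fully deterministic: in each of the
six frame/strand combinations, an ORF runs from the first start codon
(ATG/GTG/TTG) after the previous stop (or the sequence edge) to the next
in-frame stop, inclusive.  ORFs reaching a contig edge without a stop are kept
and flagged.  Codons containing ambiguous bases are never starts, never stops,
and abort any open reading frame.  This replaces a trained gene caller: the
density-delta signal depends on the stop-codon landscape, not on start-site
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

from .genetic_codes import CODE_11, CODE_25, GeneticCode, reverse_complement

__all__ = [
    "Orf",
    "CodeProfile",
    "TerminusReport",
    "find_orfs",
    "coding_density",
    "profile_code",
    "analyze_termini",
    "interval_union_length",
    "DEFAULT_MIN_ORF_LEN",
    "DEFAULT_SIZE_FLOOR",
    "DEFAULT_DELTA_THRESHOLD",
    "DEFAULT_TERMINUS_WINDOW",
]

DEFAULT_MIN_ORF_LEN = 90  # nt, including the terminal stop codon
DEFAULT_SIZE_FLOOR = 20_000  # bp; smaller sequences are not code-called
DEFAULT_DELTA_THRESHOLD = 10.0  # percentage points of coding density
DEFAULT_TERMINUS_WINDOW = 10  # codons scanned downstream for backup stops

_ACGT = frozenset("ACGT")
_CANONICAL_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Orf:
    """A predicted coding interval, in forward-strand 0-based half-open coords.

    ``end - start`` is divisible by 3 and includes the terminal stop codon
    when ``has_terminal_stop``.  ``frame`` is strand-local (0..2 counted from
    the 5' end of the coding strand).  ``inframe_tga`` holds forward-strand
    leftmost coordinates of TGA codons interior to the ORF (never the terminal
    stop); under code 11 it is empty by construction because TGA terminates
    the ORF.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    code_id: int
    has_terminal_stop: bool
    inframe_tga: Tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodeProfile:
    """Dual-code coding densities and the resulting genetic-code call.

    ``delta`` is ``(d25 - d11) * 100`` in percentage points.  Sequences at or
    below the size floor are too short for the density contrast to be
    reliable and are called ``not_evaluated``; above it, a delta of at least
    the threshold (default 10 points) calls ``code25``, anything smaller
    ``code11_compatible``.
    """

    seq_id: str
    length_bp: int
    d11: float
    d25: float
    delta: float
    call: Literal["code25", "code11_compatible", "not_evaluated"]


@dataclass(frozen=True)
class TerminusReport:
    """Stop-codon arrangement at one ORF terminus.

    ``backup_stops`` lists canonical stop codons found in-frame within
    ``window`` codons downstream of the terminal stop, as (codon, offset)
    pairs with offset counted in codons (1 = immediately after the stop).
    ``code11_viable_terminus`` is true when the terminus functions under a
    two-stop translator as well as the three-stop one: the terminal stop is a
    shared TAA/TAG, or a backup TAA/TAG sits within the window so read-through
    of a TGA stop still terminates promptly.  An ORF is fully
    ``code11_translatable`` only if it also has no in-frame TGA.
    """

    orf: Orf
    terminal_stop_codon: str  # TAA | TAG | TGA | none
    backup_stops: Tuple[Tuple[str, int], ...]
    code11_viable_terminus: bool
    code11_translatable: bool


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty sequence."""


def _scan_strand(
    s: str,
    n: int,
    code: GeneticCode,
    min_orf_len: int,
    strand: str,
    seq_id: str,
) -> List[Orf]:
    """Call ORFs on one strand.  `s` is the coding-strand sequence (rc for -)."""
    orfs: List[Orf] = []
    starts = code.start_codons
    for frame in range(3):
        pending: Optional[int] = None  # strand-local start of the open ORF
        tgas: List[int] = []  # strand-local TGA codon starts inside open ORF
        last_codon_end = frame
        for i in range(frame, n - 2, 3):
            codon = s[i : i + 3]
            last_codon_end = i + 3
            if not _ACGT.issuperset(codon):
                # ambiguous codon: aborts any open ORF, never starts one
                pending = None
                tgas = []
                continue
            if code.is_stop(codon):
                if pending is not None:
                    orfs.append(
                        _mk_orf(seq_id, pending, i + 3, strand, frame, code,
                                n, True, tgas, min_orf_len)
                    )
                pending = None
                tgas = []
            else:
                if pending is None:
                    if codon in starts:
                        pending = i
                        tgas = []
                elif codon == "TGA":
                    tgas.append(i)
        if pending is not None and last_codon_end - pending >= 3:
            orfs.append(
                _mk_orf(seq_id, pending, last_codon_end, strand, frame, code,
                        n, False, tgas, min_orf_len)
            )
    return [o for o in orfs if o is not None]


def _mk_orf(
    seq_id: str,
    s_start: int,
    s_end: int,
    strand: str,
    frame: int,
    code: GeneticCode,
    n: int,
    has_stop: bool,
    tgas: Sequence[int],
    min_orf_len: int,
) -> Optional[Orf]:
    if s_end - s_start < min_orf_len:
        return None
    if strand == "+":
        start, end = s_start, s_end
        fwd_tgas = tuple(sorted(tgas))
    else:
        start, end = n - s_end, n - s_start
        fwd_tgas = tuple(sorted(n - p - 3 for p in tgas))
    return Orf(
        seq_id=seq_id,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        code_id=code.code_id,
        has_terminal_stop=has_stop,
        inframe_tga=fwd_tgas,
    )


def find_orfs(
    seq: str,
    code: GeneticCode,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    seq_id: str = "seq",
) -> List[Orf]:
    """Call all maximal ORFs in the six frames of ``seq`` under ``code``.

    Returns ORFs of at least ``min_orf_len`` nt (interval length, terminal
    stop included), sorted by (start, end, strand).
    """
    if len(seq) == 0:
        raise EmptyInputError("cannot call ORFs on an empty sequence")
    if min_orf_len % 3 != 0:
        raise ValueError(f"min_orf_len must be divisible by 3, got {min_orf_len}")
    up = seq.upper()
    n = len(up)
    orfs = _scan_strand(up, n, code, min_orf_len, "+", seq_id)
    orfs += _scan_strand(reverse_complement(up), n, code, min_orf_len, "-", seq_id)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def interval_union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    """Total length covered by a set of half-open intervals (union, not sum)."""
    if not intervals:
        return 0
    merged = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged += cur_e - cur_s
            cur_s, cur_e = s, e
    merged += cur_e - cur_s
    return merged


def coding_density(
    seq: str,
    code: GeneticCode,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> float:
    """Fraction of ``seq`` covered by the union of ORFs on both strands."""
    orfs = find_orfs(seq, code, min_orf_len=min_orf_len)
    covered = interval_union_length([(o.start, o.end) for o in orfs])
    return covered / len(seq)


def profile_code(
    seq: str,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    size_floor: int = DEFAULT_SIZE_FLOOR,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    seq_id: str = "seq",
) -> CodeProfile:
    """Profile a sequence's genetic code from its dual-code coding densities."""
    d11 = coding_density(seq, CODE_11, min_orf_len=min_orf_len)
    d25 = coding_density(seq, CODE_25, min_orf_len=min_orf_len)
    delta = (d25 - d11) * 100.0
    if len(seq) <= size_floor:
        call = "not_evaluated"
    elif delta >= delta_threshold:
        call = "code25"
    else:
        call = "code11_compatible"
    return CodeProfile(
        seq_id=seq_id,
        length_bp=len(seq),
        d11=d11,
        d25=d25,
        delta=delta,
        call=call,
    )


def _downstream_codon(seq: str, orf: Orf, offset: int) -> Optional[str]:
    """The in-frame codon `offset` codons past the terminal stop, read 5'->3'
    on the coding strand; None when it would run off the sequence."""
    if orf.strand == "+":
        s = orf.end + 3 * (offset - 1)
        if s + 3 > len(seq):
            return None
        return seq[s : s + 3]
    s = orf.start - 3 * offset
    if s < 0:
        return None
    return reverse_complement(seq[s : s + 3])


def analyze_termini(
    seq: str,
    orfs: Sequence[Orf],
    window: int = DEFAULT_TERMINUS_WINDOW,
) -> List[TerminusReport]:
    """Inspect the stop-codon arrangement at each ORF terminus.

    One report per ORF.  Edge ORFs (no terminal stop) report codon ``"none"``
    and are never viable.  For stopped ORFs the terminal codon is read on the
    coding strand and the ``window`` in-frame codons downstream are scanned
    for canonical stop codons, which the report lists as backup stops.
    """
    up = seq.upper()
    reports: List[TerminusReport] = []
    for orf in orfs:
        if orf.start < 0 or orf.end > len(up):
            raise IndexError(
                f"ORF [{orf.start}, {orf.end}) outside sequence of length {len(up)}"
            )
        if not orf.has_terminal_stop:
            reports.append(
                TerminusReport(orf, "none", (), False, False)
            )
            continue
        if orf.strand == "+":
            terminal = up[orf.end - 3 : orf.end]
        else:
            terminal = reverse_complement(up[orf.start : orf.start + 3])
        backups: List[Tuple[str, int]] = []
        for off in range(1, window + 1):
            codon = _downstream_codon(up, orf, off)
            if codon is None:
                break
            if codon in _CANONICAL_STOPS:
                backups.append((codon, off))
        viable = terminal in ("TAA", "TAG") or any(
            c in ("TAA", "TAG") for c, _ in backups
        )
        reports.append(
            TerminusReport(
                orf=orf,
                terminal_stop_codon=terminal,
                backup_stops=tuple(backups),
                code11_viable_terminus=viable,
                code11_translatable=viable and not orf.inframe_tga,
            )
        )
    return reports
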