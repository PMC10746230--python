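"""Codon translation tables for genetic codes 11, 25 and 4.

The standard bacterial code (11) treats TAA/TAG/TGA as stops.  Gracilibacteria
and Absconditabacteria instead read TGA as glycine (code 25); some phages and
mycoplasmas read it as tryptophan (code 4).  Every downstream stage of the
pipeline — ORF calling, coding-density profiling, terminus analysis — takes one
of these :class:`GeneticCode` objects, so the stop-codon set is defined in
exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Literal

__all__ = [
    "GeneticCode",
    "CODE_11",
    "CODE_25",
    "CODE_4",
    "get_code",
    "translate",
    "stop_positions",
    "reverse_complement",
    "AmbiguousBaseError",
    "FrameError",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard bacterial/archaeal code (NCBI table 11), written out codon by codon.
_TABLE_11: Dict[str, str] = {}
_AA_ORDER = (
    "KNKN" "TTTT" "RSRS" "IIMI"  # AAx ACx AGx ATx
    "QHQH" "PPPP" "RRRR" "LLLL"  # CAx CCx CGx CTx
    "EDED" "AAAA" "GGGG" "VVVV"  # GAx GCx GGx GTx
    "*Y*Y" "SSSS" "*CWC" "LFLF"  # TAx TCx TGx TTx
)
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _TABLE_11[_b1 + _b2 + _b3] = _AA_ORDER[_i]
            _i += 1
del _i, _b1, _b2, _b3


class AmbiguousBaseError(ValueError):
    """A non-ACGT character where an unambiguous base is required."""


class FrameError(ValueError):
    """Sequence length incompatible with whole-codon translation."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table with an explicit stop-codon set.

    Attributes
    ----------
    code_id:
        Numeric translation-table identifier (11, 25 or 4).
    table:
        Mapping of all 64 DNA codons to single-letter amino acids; stop
        codons map to ``'*'``.
    stops:
        The codons this code terminates translation at.
    """

    code_id: int
    table: Dict[str, str]
    stops: FrozenSet[str]
    start_codons: FrozenSet[str] = field(default=frozenset({"ATG", "GTG", "TTG"}))

    def __post_init__(self) -> None:
        if set(self.table) != {a + b + c for a in _BASES for b in _BASES for c in _BASES}:
            raise ValueError("table must cover exactly the 64 ACGT codons")
        sense = {c for c, aa in self.table.items() if aa != "*"}
        if self.stops & sense:
            raise ValueError("stop set overlaps sense codons")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode(code_id={self.code_id}, stops={sorted(self.stops)})"


def _make_code(code_id: int) -> GeneticCode:
    table = dict(_TABLE_11)
    if code_id == 11:
        stops = frozenset({"TAA", "TAG", "TGA"})
    elif code_id == 25:
        table["TGA"] = "G"
        stops = frozenset({"TAA", "TAG"})
    elif code_id == 4:
        table["TGA"] = "W"
        stops = frozenset({"TAA", "TAG"})
    else:
        raise KeyError(f"unsupported genetic code id: {code_id}")
    return GeneticCode(code_id=code_id, table=table, stops=stops)


CODE_11 = _make_code(11)
CODE_25 = _make_code(25)
CODE_4 = _make_code(4)

_CODES = {11: CODE_11, 25: CODE_25, 4: CODE_4}


def get_code(code_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for a numeric table id (11, 25 or 4)."""
    try:
        return _CODES[int(code_id)]
    except (KeyError, ValueError):
        raise KeyError(f"unsupported genetic code id: {code_id}") from None


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (N is preserved, case is preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean(seq: str) -> str:
    """Uppercase and validate a DNA string, naming the first bad position."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _BASES:
            raise AmbiguousBaseError(
                f"non-ACGT character {ch!r} at position {i}"
            )
    return up


def translate(
    seq: str,
    code: GeneticCode,
    stop_policy: Literal["truncate", "mark"] = "mark",
) -> str:
    """Translate an in-frame DNA string.

    Parameters
    ----------
    seq:
        DNA over A/C/G/T (case-insensitive), length divisible by 3.
    code:
        Genetic code to translate under.
    stop_policy:
        ``"mark"`` emits ``'*'`` for stop codons; ``"truncate"`` ends the
        protein before the first stop.
    """
    up = _clean(seq)
    if len(up) % 3 != 0:
        raise FrameError(f"sequence length {len(up)} is not divisible by 3")
    if stop_policy not in ("truncate", "mark"):
        raise ValueError(f"unknown stop_policy: {stop_policy!r}")
    out: List[str] = []
    for i in range(0, len(up), 3):
        codon = up[i : i + 3]
        if code.is_stop(codon):
            if stop_policy == "truncate":
                break
            out.append("*")
        else:
            out.append(code.table[codon])
    return "".join(out)


def stop_positions(
    seq: str,
    code: GeneticCode,
    frame: int,
    strand: str = "+",
) -> List[int]:
    """0-based forward-strand start positions of stop codons in one frame.

    For ``strand == '-'`` the frame is counted from the 3' end of the forward
    strand (i.e. frame 0 starts at the last base), and each reported position
    is the leftmost forward-strand coordinate of the 3-nt codon.  The list is
    strictly increasing in all cases.
    """
    up = _clean(seq)
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = len(up)
    positions: List[int] = []
    if strand == "+":
        for i in range(frame, n - 2, 3):
            if code.is_stop(up[i : i + 3]):
                positions.append(i)
    else:
        rc = reverse_complement(up)
        for i in range(frame, n - 2, 3):
            if code.is_stop(rc[i : i + 3]):
                # codon occupies rc[i:i+3] == forward [n-i-3, n-i)
                positions.append(n - i - 3)
        positions.reverse()
    return positions
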