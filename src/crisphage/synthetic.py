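"""Seed-reproducible synthetic genomes, CRISPR arrays and phages with ground truth.

The generator emulates the sequence features the pipeline detects, at the
scale of single contigs:

- protein-coding genes written under genetic code 11 or 25.  Code-25 genes
  write a configurable fraction of their glycines as TGA, producing the
  in-frame TGA density that collapses code-11 coding density on such genomes;
- stop-codon-rich random intergenic sequence, so standard-code ORFs
  terminate promptly outside genes;
- optional TAA/TAG backup stops planted in-frame shortly downstream of gene
  termini (the dual-code-viable terminus arrangement);
- CRISPR arrays (identical repeat copies separated by unique random spacers)
  and labelled cas operons spliced into intergenic positions;
- phage genomes carrying protospacers copied from host array spacers with a
  scheduled number of injected substitutions, plus decoy phages with none.

Injected protospacer mismatches are placed at interior spacer positions,
outside the terminal margin that coverage-based matching may truncate, so
the scheduled mismatch count is exactly the effective one.

Every output is a pure function of its spec (including the seed): the same
spec yields byte-identical sequence and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cas import CasGene
from .genetic_codes import reverse_complement

__all__ = [
    "ArraySpec",
    "CasOperonSpec",
    "GenomeSpec",
    "ProtospacerPlant",
    "PhageSpec",
    "ArrayTruth",
    "GenomeTruth",
    "ProtospacerTruth",
    "PhageTruth",
    "SmallWorld",
    "generate_genome",
    "generate_phage",
    "generate_phage_set",
    "make_small_world",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS_11 = ("TAA", "TAG", "TGA")
_STOPS_2 = ("TAA", "TAG")

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_11 = [c for c in _ALL_CODONS if c not in _STOPS_11]  # 61 codons

# Typical prokaryotic proteome amino-acid frequencies (percent, approximate).
# The modelled lineages and their phages are strongly AT-rich; amino-acid
# composition is held realistic while codon choice within each amino acid is
# AT-biased (see _codon_machinery), which keeps off-frame stop-codon density
# high the way real AT-rich coding sequence does.
_AA_FREQS = {
    "L": 10.0, "A": 8.9, "G": 7.4, "V": 6.9, "E": 6.2, "I": 6.0, "K": 5.9,
    "S": 5.8, "R": 5.5, "D": 5.4, "T": 5.4, "P": 4.9, "N": 4.1, "Q": 3.9,
    "F": 3.9, "Y": 2.9, "M": 2.4, "H": 2.3, "C": 1.2, "W": 1.0,
}

DEFAULT_AT_CONTENT = 0.70  # intergenic base composition
DEFAULT_CODON_AT_BIAS = 4.0  # relative weight per A/T base in codon choice

_machinery_cache: dict = {}


def _codon_machinery(at_bias: float, aa_freqs_key: Optional[tuple]):
    """Sampling tables: amino-acid probabilities and per-amino-acid codon
    choice weighted by ``at_bias`` per A/T base.  Cached; ``aa_freqs_key``
    is a hashable ((aa, freq), ...) override or None for the default."""
    key = (at_bias, aa_freqs_key)
    if key in _machinery_cache:
        return _machinery_cache[key]
    from .genetic_codes import CODE_11

    freqs = dict(_AA_FREQS) if aa_freqs_key is None else dict(aa_freqs_key)
    aas = sorted(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    p /= p.sum()
    codon_lists = []
    codon_cums = []
    for aa in aas:
        codons = [c for c in _SENSE_11 if CODE_11.table[c] == aa]
        w = np.array(
            [at_bias ** (c.count("A") + c.count("T")) for c in codons],
            dtype=float,
        )
        w /= w.sum()
        codon_lists.append(codons)
        codon_cums.append(np.cumsum(w))
    out = (aas, p, codon_lists, codon_cums)
    _machinery_cache[key] = out
    return out

# rough cas gene lengths (nt, multiple of 3) for operon synthesis
_CAS_GENE_LEN = {
    "cas9": 3000, "csn2": 600, "cas1": 900, "cas2": 300,
    "cpf1": 3600, "cas4": 600, "cas10": 2400, "cas7": 900,
    "cas5": 702, "csm2": 402, "cmr5": 402, "other": 600,
}


@dataclass(frozen=True)
class ArraySpec:
    """A CRISPR array to plant: identical repeat copies around unique spacers."""

    repeat: Optional[str] = None  # random 30-mer when None
    spacers: Optional[Tuple[str, ...]] = None  # random when None
    n_spacers: int = 5
    repeat_len: int = 30
    spacer_len: int = 32


@dataclass(frozen=True)
class CasOperonSpec:
    """A cas operon to plant, as an ordered tuple of gene labels."""

    labels: Tuple[str, ...]


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint of one synthetic bacterial genome contig."""

    genome_id: str
    length: int
    code_id: int = 11
    gene_fraction: float = 0.90
    mean_gene_len: int = 900  # nt
    mean_intergenic_len: Optional[int] = None  # derived from gene_fraction
    tga_gly_fraction: float = 0.0  # forced to 0 under code 11
    backup_stop_prob: float = 0.9
    backup_window: int = 10  # codons
    at_content: float = DEFAULT_AT_CONTENT
    codon_at_bias: float = DEFAULT_CODON_AT_BIAS
    aa_freqs: Optional[Tuple[Tuple[str, float], ...]] = None  # usage hook
    arrays: Tuple[ArraySpec, ...] = ()
    cas_operons: Tuple[CasOperonSpec, ...] = ()
    seed: int = 0

    def effective_tga_fraction(self) -> float:
        return self.tga_gly_fraction if self.code_id == 25 else 0.0

    def intergenic_len(self) -> int:
        if self.mean_intergenic_len is not None:
            return self.mean_intergenic_len
        f = min(max(self.gene_fraction, 0.05), 0.98)
        return max(45, int(round(self.mean_gene_len * (1.0 - f) / f)))


@dataclass(frozen=True)
class ProtospacerPlant:
    """One protospacer to copy into a phage, with scheduled substitutions."""

    spacer_id: str
    sequence: str
    mismatches: int = 0
    strand: Optional[str] = None  # random when None


@dataclass(frozen=True)
class PhageSpec:
    """Blueprint of one synthetic phage genome."""

    phage_id: str
    length: int
    code_id: int = 11
    gene_fraction: float = 0.90
    mean_gene_len: int = 900
    tga_gly_fraction: float = 0.0
    backup_stop_prob: float = 0.9
    at_content: float = DEFAULT_AT_CONTENT
    codon_at_bias: float = DEFAULT_CODON_AT_BIAS
    protospacers: Tuple[ProtospacerPlant, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class ArrayTruth:
    start: int
    end: int
    repeat: str
    repeats: Tuple[Tuple[int, str], ...]
    spacers: Tuple[Tuple[int, str], ...]


@dataclass(frozen=True)
class GenomeTruth:
    genome_id: str
    length: int
    code_id: int
    genes: Tuple[Tuple[int, int, str], ...]  # (start, end, strand)
    arrays: Tuple[ArrayTruth, ...]
    cas_genes: Tuple[CasGene, ...]


@dataclass(frozen=True)
class ProtospacerTruth:
    phage_id: str
    spacer_id: str
    spacer_sequence: str
    start: int
    end: int
    strand: str
    mismatches: int
    mismatch_positions: Tuple[int, ...]  # spacer coordinates


@dataclass(frozen=True)
class PhageTruth:
    phage_id: str
    length: int
    code_id: int
    genes: Tuple[Tuple[int, int, str], ...]
    protospacers: Tuple[ProtospacerTruth, ...]


def _random_bases(
    rng: np.random.Generator, n: int, at: float = DEFAULT_AT_CONTENT
) -> str:
    """Random DNA with the given AT fraction (A=T, C=G)."""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


def _gene_coding(
    rng: np.random.Generator,
    n_codons: int,
    code_id: int,
    tga_gly_fraction: float,
    at_bias: float = DEFAULT_CODON_AT_BIAS,
    aa_freqs_key: Optional[tuple] = None,
) -> str:
    """Interior codons of one gene.

    Amino acids are drawn from a typical prokaryotic frequency table (or the
    spec's override), codons within each amino acid with an AT-rich bias;
    under code 25 each glycine is written as TGA with probability
    ``tga_gly_fraction``.
    """
    if n_codons <= 0:
        return ""
    aas, p, codon_lists, codon_cums = _codon_machinery(at_bias, aa_freqs_key)
    aa_idx = rng.choice(len(aas), size=n_codons, p=p)
    u = rng.random(n_codons)
    codons: List[str] = [""] * n_codons
    for k in range(len(aas)):
        sel = np.nonzero(aa_idx == k)[0]
        if sel.size == 0:
            continue
        cl = codon_lists[k]
        cidx = np.minimum(
            np.searchsorted(codon_cums[k], u[sel], side="right"), len(cl) - 1
        )
        for i, j in zip(sel.tolist(), cidx.tolist()):
            codons[i] = cl[j]
    if code_id == 25 and tga_gly_fraction > 0:
        gly = aas.index("G")
        reassign = (aa_idx == gly) & (rng.random(n_codons) < tga_gly_fraction)
        for i in np.nonzero(reassign)[0]:
            codons[i] = "TGA"
    return "".join(codons)


def _make_gene(
    rng: np.random.Generator,
    mean_gene_len: int,
    code_id: int,
    tga_gly_fraction: float,
    backup_stop_prob: float,
    backup_window: int,
    at_content: float = DEFAULT_AT_CONTENT,
    at_bias: float = DEFAULT_CODON_AT_BIAS,
    aa_freqs_key: Optional[tuple] = None,
) -> Tuple[str, int, str]:
    """One gene plus its downstream backup-stop pad, on the coding strand.

    Returns (block sequence, gene length within block, pad) where the gene
    occupies the block prefix and the pad (possibly empty) follows it.
    """
    mean_codons = max(mean_gene_len // 3, 40)
    n_codons = int(np.clip(rng.normal(mean_codons, mean_codons / 4), 30, 2 * mean_codons))
    start = ("ATG", "ATG", "ATG", "GTG", "TTG")[rng.integers(0, 5)]
    body = _gene_coding(
        rng, n_codons - 2, code_id, tga_gly_fraction, at_bias, aa_freqs_key
    )
    stops = _STOPS_2 if code_id == 25 else _STOPS_11
    stop = stops[rng.integers(0, len(stops))]
    gene = start + body + stop
    pad = ""
    if rng.random() < backup_stop_prob:
        offset = int(rng.integers(1, backup_window + 1))
        pad = (
            _random_bases(rng, 3 * (offset - 1), at_content)
            + _STOPS_2[rng.integers(0, 2)]
        )
    return gene + pad, len(gene), pad


def _other_base(b: str) -> str:
    return "C" if b == "A" else "A"


def _make_array(
    rng: np.random.Generator,
    spec: ArraySpec,
    at_content: float = DEFAULT_AT_CONTENT,
) -> Tuple[str, str, Tuple[str, ...]]:
    """Array block with 30-nt flanking guards.

    Repeat boundaries must be inferable: if every base immediately flanking
    the repeat copies were identical by chance, any detector would extend
    the repeat one column into the spacers.  The guards are adjusted so the
    flanking columns are never unanimous, keeping the planted decomposition
    the unique maximal one.
    """
    repeat = (
        spec.repeat.upper()
        if spec.repeat
        else _random_bases(rng, spec.repeat_len, at_content)
    )
    if spec.spacers is not None:
        spacers = tuple(s.upper() for s in spec.spacers)
    else:
        spacers = tuple(
            _random_bases(rng, spec.spacer_len, at_content)
            for _ in range(spec.n_spacers)
        )
    left = _random_bases(rng, 30, at_content)
    right = _random_bases(rng, 30, at_content)
    if len({sp[-1] for sp in spacers} | {left[-1]}) == 1:
        left = left[:-1] + _other_base(left[-1])
    if len({sp[0] for sp in spacers} | {right[0]}) == 1:
        right = _other_base(right[0]) + right[1:]
    parts = [left, repeat]
    for sp in spacers:
        parts.append(sp)
        parts.append(repeat)
    parts.append(right)
    return "".join(parts), repeat, spacers


def generate_genome(spec: GenomeSpec) -> Tuple[str, GenomeTruth]:
    """Synthesize one genome contig and its planted truth.

    Genes alternate with random intergenic sequence until the target length
    is reached; planted arrays and cas operons (with 30-nt intergenic guards)
    are spliced between gene blocks at seeded random positions.
    """
    rng = np.random.default_rng(spec.seed)
    tga_frac = spec.effective_tga_fraction()
    mean_ig = spec.intergenic_len()
    at = spec.at_content
    bias = spec.codon_at_bias
    aa_key = spec.aa_freqs

    # pre-build special blocks so the core can budget for them
    specials: List[Tuple[str, str, object]] = []  # (kind, seq, meta)
    for aspec in spec.arrays:
        block, repeat, spacers = _make_array(rng, aspec, at)
        specials.append(("array", block, (repeat, spacers)))
    for ospec in spec.cas_operons:
        parts: List[str] = [_random_bases(rng, 30, at)]
        gene_meta: List[Tuple[int, int, str]] = []  # relative (start, end, label)
        pos = 30
        for label in ospec.labels:
            glen = _CAS_GENE_LEN.get(label, 600)
            body = _gene_coding(rng, glen // 3 - 2, spec.code_id, tga_frac, bias, aa_key)
            stops = _STOPS_2 if spec.code_id == 25 else _STOPS_11
            gene = "ATG" + body + stops[rng.integers(0, len(stops))]
            gene_meta.append((pos, pos + len(gene), label))
            parts.append(gene)
            pos += len(gene)
            gap = _random_bases(rng, 21, at)
            parts.append(gap)
            pos += len(gap)
        parts.append(_random_bases(rng, 9, at))
        specials.append(("cas", "".join(parts), gene_meta))

    special_total = sum(len(s) for _, s, _ in specials)
    core_target = spec.length - special_total
    if core_target < 2 * spec.mean_gene_len:
        raise ValueError(
            f"genome length {spec.length} too small for planted elements "
            f"({special_total} bp)"
        )

    # core: intergenic / gene alternation
    core: List[Tuple[str, str, object]] = []  # (kind, seq, meta)
    cum = 0
    while True:
        ig_len = max(30, int(rng.normal(mean_ig, mean_ig / 3)))
        block, gene_len, _pad = _make_gene(
            rng, spec.mean_gene_len, spec.code_id, tga_frac,
            spec.backup_stop_prob, spec.backup_window,
            at, bias, aa_key,
        )
        if cum + ig_len + len(block) > core_target:
            break
        core.append(("intergenic", _random_bases(rng, ig_len, at), None))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            # pad precedes the gene on the forward strand after rc
            core.append(("gene", reverse_complement(block), (len(block) - gene_len, len(block), "-")))
        else:
            core.append(("gene", block, (0, gene_len, "+")))
        cum += ig_len + len(block)
    core.append(("intergenic", _random_bases(rng, core_target - cum, at), None))

    # splice specials after seeded intergenic blocks
    ig_indices = [i for i, (kind, _, _) in enumerate(core) if kind == "intergenic"]
    if specials:
        if len(ig_indices) < len(specials):
            raise ValueError("not enough intergenic slots for planted elements")
        slots = sorted(
            rng.choice(len(ig_indices), size=len(specials), replace=False).tolist()
        )
        for slot, special in zip(reversed(slots), reversed(specials)):
            core.insert(ig_indices[slot] + 1, special)

    # concatenate, recording truth coordinates
    parts: List[str] = []
    genes: List[Tuple[int, int, str]] = []
    arrays: List[ArrayTruth] = []
    cas_genes: List[CasGene] = []
    pos = 0
    for kind, seq, meta in core:
        if kind == "gene":
            g_start, g_end, strand = meta
            genes.append((pos + g_start, pos + g_end, strand))
        elif kind == "array":
            repeat, spacers = meta
            rlen = len(repeat)
            a_start = pos + 30
            repeats = []
            spacer_coords = []
            p = a_start
            repeats.append((p, repeat))
            for sp in spacers:
                p += rlen
                spacer_coords.append((p, sp))
                p += len(sp)
                repeats.append((p, repeat))
            arrays.append(
                ArrayTruth(
                    start=a_start,
                    end=p + rlen,
                    repeat=repeat,
                    repeats=tuple(repeats),
                    spacers=tuple(spacer_coords),
                )
            )
        elif kind == "cas":
            for g_start, g_end, label in meta:
                cas_genes.append(
                    CasGene(
                        genome_id=spec.genome_id,
                        seq_id=spec.genome_id,
                        start=pos + g_start,
                        end=pos + g_end,
                        strand="+",
                        label=label,
                    )
                )
                genes.append((pos + g_start, pos + g_end, "+"))
        parts.append(seq)
        pos += len(seq)

    seq = "".join(parts)
    truth = GenomeTruth(
        genome_id=spec.genome_id,
        length=len(seq),
        code_id=spec.code_id,
        genes=tuple(genes),
        arrays=tuple(arrays),
        cas_genes=tuple(cas_genes),
    )
    return seq, truth


def _mutate_interior(
    rng: np.random.Generator,
    spacer: str,
    n_mismatches: int,
    min_coverage: float = 0.95,
) -> Tuple[str, Tuple[int, ...]]:
    """Substitute bases at interior positions only, so terminal truncation at
    the matcher's coverage floor cannot shed a scheduled mismatch."""
    L = len(spacer)
    margin = L - math.ceil(min_coverage * L)
    lo, hi = margin, L - margin
    if hi - lo < n_mismatches:
        raise ValueError("spacer too short for scheduled interior mismatches")
    positions = sorted(
        rng.choice(np.arange(lo, hi), size=n_mismatches, replace=False).tolist()
    )
    out = list(spacer)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out), tuple(positions)


def generate_phage(spec: PhageSpec) -> Tuple[str, PhageTruth]:
    """Synthesize one phage genome, planting its scheduled protospacers."""
    gspec = GenomeSpec(
        genome_id=spec.phage_id,
        length=spec.length,
        code_id=spec.code_id,
        gene_fraction=spec.gene_fraction,
        mean_gene_len=spec.mean_gene_len,
        tga_gly_fraction=spec.tga_gly_fraction,
        backup_stop_prob=spec.backup_stop_prob,
        at_content=spec.at_content,
        codon_at_bias=spec.codon_at_bias,
        seed=spec.seed,
    )
    seq, gtruth = generate_genome(gspec)
    rng = np.random.default_rng(spec.seed + 777)
    chars = list(seq)
    occupied: List[Tuple[int, int]] = []
    planted: List[ProtospacerTruth] = []
    for plant in spec.protospacers:
        spacer = plant.sequence.upper()
        L = len(spacer)
        mutated, positions = _mutate_interior(rng, spacer, plant.mismatches)
        strand = plant.strand or ("+" if rng.random() < 0.5 else "-")
        inserted = mutated if strand == "+" else reverse_complement(mutated)
        for _attempt in range(1000):
            start = int(rng.integers(50, len(seq) - L - 50))
            if all(start + L <= s or start >= e for s, e in occupied):
                break
        else:  # pragma: no cover - capacity exhausted
            raise ValueError("could not place protospacer without overlap")
        occupied.append((start, start + L))
        chars[start : start + L] = inserted
        planted.append(
            ProtospacerTruth(
                phage_id=spec.phage_id,
                spacer_id=plant.spacer_id,
                spacer_sequence=spacer,
                start=start,
                end=start + L,
                strand=strand,
                mismatches=plant.mismatches,
                mismatch_positions=positions,
            )
        )
    return "".join(chars), PhageTruth(
        phage_id=spec.phage_id,
        length=len(seq),
        code_id=spec.code_id,
        genes=gtruth.genes,
        protospacers=tuple(planted),
    )


def generate_phage_set(
    specs: Sequence[PhageSpec],
) -> Tuple[Dict[str, str], Dict[str, PhageTruth]]:
    """Generate a phage collection; decoy phages simply plant nothing."""
    seqs: Dict[str, str] = {}
    truths: Dict[str, PhageTruth] = {}
    for spec in specs:
        seq, truth = generate_phage(spec)
        seqs[spec.phage_id] = seq
        truths[spec.phage_id] = truth
    return seqs, truths


@dataclass
class SmallWorld:
    """A fully specified miniature study: hosts, phages and expectations."""

    genomes: Dict[str, str]
    phages: Dict[str, str]
    genome_truth: Dict[str, GenomeTruth]
    phage_truth: Dict[str, PhageTruth]
    host_groups: Dict[str, str]
    cas_genes: List[CasGene]
    expected_links: Dict[str, set]  # phage -> set of source genome ids
    expected_cotargeted: List[str]
    expected_subtypes: Dict[str, Tuple[str, ...]]
    expected_code_calls: Dict[str, str]


def make_small_world(
    seed: int = 0,
    genome_length: int = 32_000,
    phage_length: int = 30_000,
) -> SmallWorld:
    """Build the canonical six-host / twelve-phage test world.

    Hosts cover all five cas subtypes plus one incomplete system, each with
    one five-spacer array.  Phages cover exact and 1-mismatch protospacers
    (linkable), 2- and 3-mismatch protospacers (not linkable), two
    co-targeted phages carrying spacer targets of both an SGA host and the
    non-SGA host, and two decoys.  Phage genetic codes split between 11 and
    25 so code calls are exercised in both directions.
    """
    base = np.random.default_rng(seed)
    child = iter(base.integers(0, 2**31 - 1, size=64).tolist())

    hosts = [
        ("sacc1", "Saccharibacteria", 11, ("cas9", "csn2", "cas1", "cas2")),
        ("sacc2", "Saccharibacteria", 11, ("cas9", "cas1", "cas2")),
        ("grac1", "Gracilibacteria", 25, ("cpf1", "cas1", "cas4", "cas2")),
        ("grac2", "Gracilibacteria", 25, ("cas10", "cas7", "cas5", "csm2")),
        ("absc1", "Absconditabacteria", 25, ("cas10", "cas7", "cas5", "cmr5")),
        ("entero1", "Firmicutes", 11, ("cas1", "cas2")),
    ]
    expected_subtypes = {
        "sacc1": ("II-A",),
        "sacc2": ("II-C1",),
        "grac1": ("V-A",),
        "grac2": ("III-A",),
        "absc1": ("III-B",),
        "entero1": ("incomplete",),
    }

    genomes: Dict[str, str] = {}
    genome_truth: Dict[str, GenomeTruth] = {}
    host_groups: Dict[str, str] = {}
    cas_genes: List[CasGene] = []
    for gid, group, code_id, labels in hosts:
        spec = GenomeSpec(
            genome_id=gid,
            length=genome_length,
            code_id=code_id,
            tga_gly_fraction=0.3 if code_id == 25 else 0.0,
            arrays=(ArraySpec(n_spacers=5),),
            cas_operons=(CasOperonSpec(labels=labels),),
            seed=next(child),
        )
        seq, truth = generate_genome(spec)
        genomes[gid] = seq
        genome_truth[gid] = truth
        host_groups[gid] = group
        cas_genes.extend(truth.cas_genes)

    def spacer(gid: str, idx: int) -> ProtospacerPlant:
        sp = genome_truth[gid].arrays[0].spacers[idx][1]
        return ProtospacerPlant(
            spacer_id=f"{gid}_a0_s{idx}", sequence=sp, mismatches=0
        )

    def spacer_mm(gid: str, idx: int, mm: int) -> ProtospacerPlant:
        sp = genome_truth[gid].arrays[0].spacers[idx][1]
        return ProtospacerPlant(
            spacer_id=f"{gid}_a0_s{idx}", sequence=sp, mismatches=mm
        )

    phage_specs = [
        PhageSpec("phiS1", phage_length, 11, protospacers=(spacer("sacc1", 0),), seed=next(child)),
        PhageSpec("phiS2", phage_length, 11, protospacers=(spacer("sacc2", 1),), seed=next(child)),
        PhageSpec("phiG1", phage_length, 25, tga_gly_fraction=0.3,
                  protospacers=(spacer("grac1", 0),), seed=next(child)),
        PhageSpec("phiG2", phage_length, 11, protospacers=(spacer("grac2", 2),), seed=next(child)),
        PhageSpec("phiA1", phage_length, 25, tga_gly_fraction=0.3,
                  protospacers=(spacer("absc1", 0),), seed=next(child)),
        PhageSpec("phiM1", phage_length, 11,
                  protospacers=(spacer_mm("sacc1", 2, 1),), seed=next(child)),
        PhageSpec("phiX1", phage_length, 11,
                  protospacers=(spacer_mm("sacc1", 3, 2),), seed=next(child)),
        PhageSpec("phiX2", phage_length, 25, tga_gly_fraction=0.3,
                  protospacers=(spacer_mm("grac1", 3, 3),), seed=next(child)),
        PhageSpec("phiC1", phage_length, 11,
                  protospacers=(spacer("sacc1", 4), spacer("entero1", 0)),
                  seed=next(child)),
        PhageSpec("phiC2", phage_length, 25, tga_gly_fraction=0.3,
                  protospacers=(spacer("absc1", 1), spacer_mm("entero1", 1, 1)),
                  seed=next(child)),
        PhageSpec("phiD1", phage_length, 11, seed=next(child)),
        PhageSpec("phiD2", phage_length, 25, tga_gly_fraction=0.3, seed=next(child)),
    ]
    phages, phage_truth = generate_phage_set(phage_specs)

    expected_links = {
        "phiS1": {"sacc1"},
        "phiS2": {"sacc2"},
        "phiG1": {"grac1"},
        "phiG2": {"grac2"},
        "phiA1": {"absc1"},
        "phiM1": {"sacc1"},
        "phiC1": {"sacc1", "entero1"},
        "phiC2": {"absc1", "entero1"},
    }
    expected_code_calls = {
        spec.phage_id: (
            "code25" if spec.code_id == 25 else "code11_compatible"
        )
        for spec in phage_specs
    }
    return SmallWorld(
        genomes=genomes,
        phages=phages,
        genome_truth=genome_truth,
        phage_truth=phage_truth,
        host_groups=host_groups,
        cas_genes=cas_genes,
        expected_links=expected_links,
        expected_cotargeted=["phiC1", "phiC2"],
        expected_subtypes=expected_subtypes,
        expected_code_calls=expected_code_calls,
    )
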