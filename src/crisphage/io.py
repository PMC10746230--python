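"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython.  Tables are plain TSV written with fixed
formatting so identical runs produce byte-identical files.  Interval
features (ORFs, CRISPR arrays) are emitted as GFF3 with 1-based inclusive
coordinates; everything in memory stays 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import CrisprArray
from .cas import CasGene
from .orfs import Orf

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_cas_tsv",
    "write_cas_genes_tsv",
    "read_host_groups",
    "write_host_groups",
    "orfs_to_gff3",
    "arrays_to_gff3",
]


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input FASTA not found: {path}")
    records: Dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id or len(rec.seq) == 0:
            raise ValueError(f"malformed FASTA record #{i} in {path}")
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, seqs: Dict[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_cas_tsv(path) -> List[CasGene]:
    """Read cas gene annotations from a TSV with columns
    genome_id, seq_id, start, end, strand, label (0-based half-open)."""
    genes: List[CasGene] = []
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if ln == 0 and fields[0] == "genome_id":
            continue
        if len(fields) < 6:
            raise ValueError(f"malformed cas TSV line {ln + 1}: {line!r}")
        genes.append(
            CasGene(
                genome_id=fields[0],
                seq_id=fields[1],
                start=int(fields[2]),
                end=int(fields[3]),
                strand=fields[4],
                label=fields[5].strip().lower(),
            )
        )
    return genes


def write_cas_genes_tsv(path, genes: Sequence[CasGene]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tseq_id\tstart\tend\tstrand\tlabel\n")
        for g in genes:
            fh.write(f"{g.genome_id}\t{g.seq_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.label}\n")


def read_host_groups(path) -> Dict[str, str]:
    """Read a 2-column TSV mapping genome_id to host lineage name."""
    groups: Dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if ln == 0 and fields[0] == "genome_id":
            continue
        if len(fields) < 2:
            raise ValueError(f"malformed host-group TSV line {ln + 1}: {line!r}")
        groups[fields[0]] = fields[1]
    return groups


def write_host_groups(path, groups: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\thost_group\n")
        for gid in groups:
            fh.write(f"{gid}\t{groups[gid]}\n")


def orfs_to_gff3(path, orfs: Sequence[Orf]) -> None:
    """Write predicted ORFs as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs):
            attrs = (
                f"ID=orf{i};code_id={o.code_id};"
                f"inframe_tga={len(o.inframe_tga)};"
                f"terminal_stop={'yes' if o.has_terminal_stop else 'no'}"
            )
            fh.write(
                f"{o.seq_id}\tcrisphage\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t0\t{attrs}\n"
            )


def arrays_to_gff3(path, arrays: Sequence[CrisprArray]) -> None:
    """Write CRISPR arrays as GFF3 repeat_region features with repeat_unit
    and spacer children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        n = 0
        for arr in arrays:
            n += 1
            aid = f"array{n}"
            fh.write(
                f"{arr.seq_id}\tcrisphage\trepeat_region\t{arr.start + 1}\t"
                f"{arr.end}\t.\t+\t.\t"
                f"ID={aid};evidence={arr.evidence_proxy};"
                f"consensus_repeat={arr.consensus_repeat};"
                f"n_spacers={arr.n_spacers}\n"
            )
            for j, (s, rep) in enumerate(arr.repeats):
                fh.write(
                    f"{arr.seq_id}\tcrisphage\trepeat_unit\t{s + 1}\t"
                    f"{s + len(rep)}\t.\t+\t.\tID={aid}.r{j};Parent={aid}\n"
                )
            for j, (s, sp) in enumerate(arr.spacers):
                fh.write(
                    f"{arr.seq_id}\tcrisphage\tspacer\t{s + 1}\t"
                    f"{s + len(sp)}\t.\t+\t.\tID={aid}.s{j};Parent={aid}\n"
                )
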