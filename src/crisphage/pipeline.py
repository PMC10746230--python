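"""End-to-end orchestration: genomes + phage candidates -> reports.

A run detects CRISPR arrays in every input genome, pools spacers from
high-confidence arrays into a dereplicated database, classifies each
genome's CRISPR-Cas subtype from its cas annotations, matches the spacer
database against every candidate phage, derives host links and co-targeted
phages, profiles each phage's genetic code from dual-code coding densities,
and summarises per-lineage system prevalence.  Outputs are plain text
(GFF3 / FASTA / TSV / JSON) and are a pure function of (inputs, config):
identical runs are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .arrays import ArrayParams, CrisprArray, SpacerDb, detect_arrays, extract_spacers
from .cas import CasGene, CasSystemCall, classify_system, crispr_budget, pool_labels
from .io import (
    arrays_to_gff3,
    read_cas_tsv,
    read_fasta,
    read_host_groups,
)
from .matching import (
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MIN_COVERAGE,
    HostLink,
    find_cotargeted,
    link_hosts,
)
from .orfs import (
    DEFAULT_DELTA_THRESHOLD,
    DEFAULT_MIN_ORF_LEN,
    DEFAULT_SIZE_FLOOR,
    CodeProfile,
    profile_code,
)

__all__ = ["RunConfig", "RunResult", "prevalence", "run_pipeline"]


def prevalence(n_with_system: int, n_genomes: int) -> float:
    """Percentage of genomes carrying a complete system, half-up to 1 decimal."""
    if n_genomes <= 0:
        raise ZeroDivisionError("n_genomes must be positive")
    if not 0 <= n_with_system <= n_genomes:
        raise ValueError(
            f"n_with_system={n_with_system} out of range for n_genomes={n_genomes}"
        )
    pct = Decimal(100 * n_with_system) / Decimal(n_genomes)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the study's published values: >=95% spacer
    coverage with <=1 mismatch for protospacer matching, a 10-point
    coding-density delta over a 20-kb size floor for the code call, and the
    high-confidence array filter of the detector.
    """

    genomes_fasta: str = ""
    phages_fasta: str = ""
    cas_tsv: Optional[str] = None
    host_groups_tsv: Optional[str] = None
    extra_spacers_tsv: Optional[str] = None
    out_dir: str = "crisphage_out"
    min_coverage: float = DEFAULT_MIN_COVERAGE
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    size_floor: int = DEFAULT_SIZE_FLOOR
    min_orf_len: int = DEFAULT_MIN_ORF_LEN
    array_params: ArrayParams = field(default_factory=ArrayParams)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["array_params"]["repeat_len"] = list(d["array_params"]["repeat_len"])
        d["array_params"]["spacer_len"] = list(d["array_params"]["spacer_len"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        ap = d.pop("array_params", None)
        cfg = cls(**d)
        if ap is not None:
            ap["repeat_len"] = tuple(ap["repeat_len"])
            ap["spacer_len"] = tuple(ap["spacer_len"])
            cfg = replace(cfg, array_params=ArrayParams(**ap))
        return cfg


@dataclass
class RunResult:
    """In-memory results of a pipeline run (files are also written)."""

    arrays: Dict[str, List[CrisprArray]]
    spacer_db: SpacerDb
    cas_calls: List[CasSystemCall]
    budgets: Dict[str, Tuple[int, float]]
    links: List[HostLink]
    cotargeted: List[Tuple[str, frozenset]]
    profiles: List[CodeProfile]
    prevalence_rows: List[Tuple[str, int, int, float]]
    out_dir: Path
    warnings: List[str]


def _write_links(out_dir: Path, links: Sequence[HostLink]) -> None:
    with open(out_dir / "hits.tsv", "w") as fh:
        fh.write(
            "target_id\tspacer_id\thost_group\tstart\tend\tstrand\t"
            "matched_len\tmismatches\tcoverage\n"
        )
        for link in links:
            for hit, group in zip(link.hits, link.host_groups):
                fh.write(
                    f"{link.target_id}\t{hit.spacer_id}\t{group}\t{hit.start}\t"
                    f"{hit.end}\t{hit.strand}\t{hit.matched_len}\t"
                    f"{hit.mismatches}\t{hit.coverage:.4f}\n"
                )
    with open(out_dir / "links.tsv", "w") as fh:
        fh.write("target_id\tn_hits\thost_groups\tsource_genomes\n")
        for link in links:
            groups = ",".join(sorted(link.group_set))
            sources = ",".join(
                sorted({h.spacer_id.rsplit("_a", 1)[0] for h in link.hits})
            )
            fh.write(f"{link.target_id}\t{len(link.hits)}\t{groups}\t{sources}\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by ``config``.

    Writes arrays.gff3, spacers.fasta, spacers.tsv, cas_calls.tsv, hits.tsv,
    links.tsv, cotargeted.tsv, code_profiles.tsv, prevalence.tsv and
    manifest.json under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collected: List[str] = []

    genomes = read_fasta(config.genomes_fasta)
    phages = read_fasta(config.phages_fasta) if config.phages_fasta else {}
    host_groups = (
        read_host_groups(config.host_groups_tsv)
        if config.host_groups_tsv
        else {gid: "unknown" for gid in genomes}
    )
    cas_genes: List[CasGene] = (
        read_cas_tsv(config.cas_tsv) if config.cas_tsv else []
    )

    # stage 1: array detection
    arrays: Dict[str, List[CrisprArray]] = {}
    for gid in genomes:
        arrays[gid] = detect_arrays(genomes[gid], seq_id=gid, params=config.array_params)
    all_arrays = [a for gid in genomes for a in arrays[gid]]
    arrays_to_gff3(out_dir / "arrays.gff3", all_arrays)

    # stage 2: spacer database
    spacer_db = extract_spacers(all_arrays, only_high=True)
    if config.extra_spacers_tsv:
        n_added = spacer_db.import_tsv(config.extra_spacers_tsv)
        collected.append(f"imported {n_added} external spacers")
    for rec in spacer_db.entries:
        if len(rec.sequence) < 20:
            collected.append(
                f"short spacer {rec.spacer_id} ({len(rec.sequence)} nt)"
            )
    spacer_db.to_fasta(out_dir / "spacers.fasta")
    spacer_db.to_tsv(out_dir / "spacers.tsv")

    # stage 3: cas subtype classification + defense budget
    pooled = pool_labels(cas_genes)
    cas_calls: List[CasSystemCall] = []
    budgets: Dict[str, Tuple[int, float]] = {}
    for gid in genomes:
        has_high = any(a.evidence_proxy == "high" for a in arrays[gid])
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            subtypes = classify_system(pooled.get(gid, []), has_high)
        collected.extend(str(w.message) for w in wlist)
        cas_calls.append(
            CasSystemCall(
                genome_id=gid,
                subtypes=subtypes,
                genes_matched=frozenset(
                    lbl for lbl in pooled.get(gid, [])
                ),
                has_high_evidence_array=has_high,
            )
        )
        cas_iv = [
            (g.start, g.end) for g in cas_genes if g.genome_id == gid
        ]
        arr_iv = [(a.start, a.end) for a in arrays[gid]]
        budgets[gid] = crispr_budget(len(genomes[gid]), cas_iv, arr_iv)
    with open(out_dir / "cas_calls.tsv", "w") as fh:
        fh.write(
            "genome_id\tsubtypes\tgenes_matched\thigh_evidence_array\t"
            "budget_bp\tbudget_fraction\n"
        )
        for call in cas_calls:
            bp, frac = budgets[call.genome_id]
            fh.write(
                f"{call.genome_id}\t{','.join(call.subtypes)}\t"
                f"{','.join(sorted(call.genes_matched))}\t"
                f"{'yes' if call.has_high_evidence_array else 'no'}\t"
                f"{bp}\t{frac:.6f}\n"
            )

    # stage 4: spacer-phage matching and host links
    groups_for_sources = dict(host_groups)
    groups_for_sources.setdefault("external", "external")
    links = link_hosts(
        spacer_db,
        phages,
        groups_for_sources,
        min_coverage=config.min_coverage,
        max_mismatch=config.max_mismatch,
    )
    _write_links(out_dir, links)

    # stage 5: co-targeting
    cotargeted = [(t, frozenset(g)) for t, g in find_cotargeted(links)]
    with open(out_dir / "cotargeted.tsv", "w") as fh:
        fh.write("target_id\thost_groups\n")
        for t, g in cotargeted:
            fh.write(f"{t}\t{','.join(sorted(g))}\n")

    # stage 6: genetic-code profiling of phages
    profiles = [
        profile_code(
            phages[pid],
            min_orf_len=config.min_orf_len,
            size_floor=config.size_floor,
            delta_threshold=config.delta_threshold,
            seq_id=pid,
        )
        for pid in sorted(phages)
    ]
    with open(out_dir / "code_profiles.tsv", "w") as fh:
        fh.write("seq_id\tlength_bp\td11\td25\tdelta\tcall\n")
        for p in profiles:
            fh.write(
                f"{p.seq_id}\t{p.length_bp}\t{p.d11:.4f}\t{p.d25:.4f}\t"
                f"{p.delta:.2f}\t{p.call}\n"
            )

    # stage 7: per-lineage prevalence
    by_group: Dict[str, List[str]] = {}
    for gid in genomes:
        by_group.setdefault(host_groups.get(gid, "unknown"), []).append(gid)
    with_system = {
        c.genome_id for c in cas_calls if c.subtypes != ("incomplete",)
    }
    prevalence_rows: List[Tuple[str, int, int, float]] = []
    for group in sorted(by_group):
        gids = by_group[group]
        n_with = sum(1 for gid in gids if gid in with_system)
        prevalence_rows.append(
            (group, len(gids), n_with, prevalence(n_with, len(gids)))
        )
    with open(out_dir / "prevalence.tsv", "w") as fh:
        fh.write("host_group\tn_genomes\tn_with_system\tprevalence_percent\n")
        for group, n, n_with, pct in prevalence_rows:
            fh.write(f"{group}\t{n}\t{n_with}\t{pct:.1f}\n")

    manifest = {
        "package": "crisphage",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "genomes": len(genomes),
            "phages": len(phages),
            "arrays": len(all_arrays),
            "spacers": len(spacer_db),
            "linked_phages": len(links),
            "cotargeted": len(cotargeted),
        },
        "warnings": sorted(collected),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        arrays=arrays,
        spacer_db=spacer_db,
        cas_calls=cas_calls,
        budgets=budgets,
        links=links,
        cotargeted=cotargeted,
        profiles=profiles,
        prevalence_rows=prevalence_rows,
        out_dir=out_dir,
        warnings=collected,
    )
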