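# crisphage

CRISPR spacer–based phage–host linking and alternative genetic-code
profiling for CPR bacteria and their phages.

## The problem

Saccharibacteria, Gracilibacteria and Absconditabacteria (collectively
"SGA") are host-dependent lineages of the bacterial Candidate Phyla
Radiation.  Little is known about the phages that infect them, for two
reasons: the phages cannot be isolated in culture, and two of the three
lineages translate with **genetic code 25**, in which the canonical stop
codon TGA encodes glycine — so standard gene callers shred their genomes.

Two sequence signals address both problems:

1. **CRISPR spacers** stored in a bacterial genome are exact records of past
   phage encounters.  A spacer match in a phage genome (a *protospacer*)
   links the phage to that bacterial host lineage.
2. **Dual-code coding density** diagnoses a genome's genetic code.  With
   coding density *d<sub>c</sub>* = fraction of the genome covered by ORFs
   predicted under code *c*, the difference

   Δd = (d₂₅ − d₁₁) × 100   [percentage points]

   is near zero for standard-coded genomes, but large for code-25 genomes,
   whose in-frame TGA codons fragment every code-11 ORF.  Genomes above a
   20 kb size floor with Δd ≥ 10 points are called `code25`; smaller Δd is
   `code11_compatible`.

`crisphage` implements this analysis end to end as a tested, reusable
library with a thin CLI: CRISPR array detection and spacer extraction,
rule-based CRISPR-Cas subtype classification (II-A, II-C1, V-A, III-A,
III-B), ungapped spacer–protospacer matching at ≥95% coverage / ≤1
mismatch, co-targeting analysis (phages hit by both SGA and non-SGA
spacers), dual-code ORF calling with in-frame TGA maps and backup-stop
terminus analysis, and per-lineage prevalence summaries.  A synthetic-data
generator produces seed-reproducible genomes, arrays, cas operons and
phages with full planted ground truth, so every stage is testable without
external databases.

## Worked example

```python
from crisphage import profile_code
from crisphage.synthetic import PhageSpec, generate_phage

alt, _ = generate_phage(PhageSpec("alt_phage", 30000, code_id=25,
                                  tga_gly_fraction=0.3, seed=7))
std, _ = generate_phage(PhageSpec("std_phage", 30000, code_id=11, seed=7))
for name, seq in (("alt_phage", alt), ("std_phage", std)):
    p = profile_code(seq, seq_id=name)
    print(f"{p.seq_id:<10} d11={p.d11:.3f} d25={p.d25:.3f} "
          f"delta={p.delta:+.1f} -> {p.call}")
```

prints

```
alt_phage  d11=0.803 d25=0.956 delta=+15.3 -> code25
std_phage  d11=0.919 d25=0.955 delta=+3.6 -> code11_compatible
```

The alternatively coded phage loses ~15 points of coding density when its
genes are read with TGA as a stop; the standard-coded phage reads almost
identically under both codes, so it could be translated by hosts using
either.  The `examples/` directory walks through each capability the same
way (translation tables, array detection, host linking and co-targeting,
the full pipeline); every script prints the numbers it computes and what
they mean.

From a shell, the same pipeline is:

```bash
crisphage simulate --seed 0 --out-dir world
crisphage run --genomes world/genomes.fasta --phages world/phages.fasta \
    --cas-tsv world/cas_genes.tsv --host-groups world/host_groups.tsv \
    --out-dir out --seed 0
```

which writes arrays (GFF3), the spacer database (FASTA/TSV), subtype calls
with defense budgets, spacer hits and host links, co-targeted phages,
dual-code profiles and prevalence tables, plus a manifest; identical
configurations produce byte-identical output trees.

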