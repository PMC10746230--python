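"""Diagnose a phage's genetic code from its dual-code coding densities.

A genome written in code 25 is dense in in-frame TGA codons, so ORF calling
under code 11 shatters its genes: its code-11 coding density collapses while
the code-25 density stays high.  The difference (delta, in percentage
points) classifies the genome; only sequences above 20 kb are called.
"""

from crisphage import CODE_25, analyze_termini, find_orfs, profile_code
from crisphage.synthetic import PhageSpec, generate_phage

alt, _ = generate_phage(
    PhageSpec("alt_phage", 30000, code_id=25, tga_gly_fraction=0.3, seed=7)
)
std, _ = generate_phage(PhageSpec("std_phage", 30000, code_id=11, seed=7))

print("phage      length   d11    d25    delta   call")
for name, seq in (("alt_phage", alt), ("std_phage", std)):
    p = profile_code(seq, seq_id=name)
    print(
        f"{p.seq_id:<10} {p.length_bp:>6}  {p.d11:.3f}  {p.d25:.3f}  "
        f"{p.delta:+6.1f}   {p.call}"
    )

# Gene termini of the standard-coded phage: where a gene ends in TGA, a
# backup TAA/TAG shortly downstream lets translation terminate correctly
# even in a host that reads TGA as glycine.
orfs = find_orfs(std, CODE_25, 90)
reports = analyze_termini(std, orfs, window=10)
with_backup = [
    r for r in reports if r.terminal_stop_codon != "none" and r.backup_stops
]
print(f"\n{len(with_backup)} of {len(reports)} ORF termini have a backup stop "
      "within 10 codons, e.g.:")
for r in with_backup[:3]:
    print(
        f"  ORF at {r.orf.start}-{r.orf.end} ({r.orf.strand}): terminal "
        f"{r.terminal_stop_codon}, backups {list(r.backup_stops)}, "
        f"dual-code viable: {r.code11_viable_terminus}"
    )
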