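"""Translate DNA under the standard and the TGA-glycine genetic codes.

Gracilibacteria and Absconditabacteria read the canonical stop codon TGA as
glycine (genetic code 25).  The same codon string therefore yields different
proteins — and different stop landscapes — under the two codes.
"""

from crisphage import CODE_11, CODE_25, stop_positions, translate

gene = "ATGAAATGGGGATGATTTGGTTAA"  # M K W G [TGA] F G *

print("codons      :", " ".join(gene[i : i + 3] for i in range(0, len(gene), 3)))
print("code 11     :", translate(gene, CODE_11, "mark"))
print("code 25     :", translate(gene, CODE_25, "mark"))
print("code 11 trunc:", translate(gene, CODE_11, "truncate"))
print("code 25 trunc:", translate(gene, CODE_25, "truncate"))

print("\nstop codon positions, frame 0, forward strand:")
print("  code 11:", stop_positions(gene, CODE_11, 0))
print("  code 25:", stop_positions(gene, CODE_25, 0))

# Under code 11 the TGA at position 12 truncates the protein after 4 residues;
# under code 25 it is a glycine and translation runs to the shared TAA stop.
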