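# Methods

This note documents the models and procedures implemented in `crisphage`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Genetic codes

Three translation tables are provided: the standard bacterial code 11
(stops TAA/TAG/TGA), code 25 (TGA → glycine; stops TAA/TAG) and code 4
(TGA → tryptophan), all derived from one explicit 64-codon table.  Codes 11
and 25 differ at exactly one codon, which is the invariant every downstream
computation leans on: the code-25 stop set is a strict subset of the
code-11 set, so code-25 ORFs can only extend or merge code-11 ORFs, and
d₂₅ ≥ d₁₁ holds for every sequence.  Input is DNA-only (U rejected);
lowercase is normalised.  Ambiguity codes are rejected by `translate` but
tolerated by ORF calling with a single policy: a codon containing a
non-ACGT base is never a start, never a stop, and aborts any open reading
frame, keeping results deterministic on assemblies with N runs.

## ORF model and coding density

ORFs are *maximal start-to-stop intervals*: in each of the six
frame/strand combinations, an ORF runs from the first start codon
(ATG/GTG/TTG) after the previous stop (or the sequence edge) to the next
in-frame stop, inclusive.  ORFs reaching a contig edge without a stop are
kept and flagged (`has_terminal_stop=False`) — fragmented assemblies
truncate genes — but are excluded from terminus analysis.  The default
minimum ORF length is 90 nt (interval length, terminal stop included),
the conventional prokaryotic floor.  This deliberately replaces a trained
gene caller (GC-frame statistics, RBS scoring): the dual-code density
contrast is carried by the stop-codon landscape, not by start-site
precision, and a closed-form ORF definition is exactly verifiable against
an enumeration oracle.

Coding density is the length of the union of all ORF intervals over both
strands divided by sequence length.  Internally all coordinates are
0-based half-open on the forward strand; GFF3 output is 1-based inclusive.
Minus-strand ORFs report forward-strand coordinates with a strand-local
frame.

### The code call

`profile_code` computes d₁₁ and d₂₅ and their difference
Δd = (d₂₅ − d₁₁) × 100 in **percentage points** (not relative change —
densities are themselves fractions, and the classification histogram's
axis is a difference of percentages; the threshold is configurable for
users who prefer a relative reading).  Sequences of ≤ 20 kb are called
`not_evaluated`: below that size the density estimate is too noisy for a
reliable call.  Above it, Δd ≥ 10 points calls `code25`, else
`code11_compatible`.  Note the asymmetry of the call names: a small Δd
does not prove code 11, it shows the genome is *compatible* with both
codes.

### Termini and backup stops

`analyze_termini` inspects the stop arrangement at each ORF terminus: the
terminal codon, and any canonical stop codons in-frame within a window
(default 10 codons) downstream, listed as backup stops.  A terminus is
dual-code viable when the terminal stop is a shared TAA/TAG or a backup
TAA/TAG lies within the window — the arrangement that lets a gene ending
in TGA still terminate correctly under a two-stop translator.  An ORF is
fully code-11-translatable only if it additionally contains no in-frame
TGA (which would truncate the code-11 product).  The function reads the
sequence directly, so it applies to ORF sets predicted under either code;
edge ORFs report terminal codon `none` and are never viable.

## CRISPR array detection

The detector is a CRT-style seed-and-extend repeat finder.  Exact 8-mers
recurring at gaps compatible with one repeat plus one spacer
(repeat 23–55 nt, spacer 20–60 nt, hence gaps of 43–115 nt) seed candidate
repeat runs of at least `min_spacers + 1` copies.  Boundaries extend
column by column while all copies agree (the agreement fraction is
configurable; the default of 1.0 makes spacer boundaries exact for
identical repeat copies and keeps detection fully deterministic).
Candidates violating the length constraints, or spanning ambiguous bases,
are dropped; overlapping candidates resolve by repeat count, then span,
then leftmost position.

Arrays are tiered by a high-confidence filter standing in for the upper
evidence levels of dedicated CRISPR finders: ≥ 3 spacers, mean repeat
identity to consensus ≥ 0.90, and maximum spacer pairwise identity < 0.60
(near-duplicate spacers suggest a tandem repeat, not a CRISPR locus).
These thresholds are a declared approximation of that tiering, not a
reimplementation of any specific tool.  Spacers from high-confidence
arrays are pooled into a database dereplicated by exact full-length string
identity.  Reverse-complement duplicates are *not* collapsed — matching
scans both strands anyway, so orientation only affects database size — and
externally derived spacers (e.g. from read-based array expansion, which is
out of scope here) can be imported from a 2-column TSV.

## Cas subtype classification and defense budget

Cas gene annotation is taken as input (TSV of labelled intervals; HMM
searching is out of scope).  Subtypes are called from the pooled label set
of a genome by explicit gene-content rules, applied in order: II-A
(cas9+csn2+cas1+cas2), II-C1 (cas9+cas1+cas2 without csn2), V-A
(cpf1+cas1+cas4+cas2), III-A (cas10+cas7+cas5+csm2), III-B
(cas10+cas7+cas5+cmr5).  All satisfied subtypes are returned — genomes
with several cas loci exist, and III-A/III-B co-fire when both csm2 and
cmr5 are present.  A system is complete only if the genome also carries a
high-confidence array; otherwise, and when no rule fires, the call is
`incomplete`.  Labels are pooled genome-wide (the rules speak of genes
"encoded within the same genome"); a per-scaffold mode is available for
fragmented assemblies where genome-wide pooling would over-call.  Unknown
labels warn and are ignored; the label `other` represents unannotated ORFs
inside cas operons and never alters a call.

The defense budget is the length of the union of cas gene and array
intervals (overlaps counted once) and its fraction of genome length.

## Spacer–protospacer matching

Matching is an exact, ungapped Hamming model mirroring short-read BLASTn
thresholds: a hit requires ≥ 95% spacer coverage with ≤ 1 substitution,
on either strand.  Coverage below 1.0 is realised by truncating the
spacer at either end — the way alignment ends erode in short-word
searches — never by interior gaps: at these lengths and thresholds a
gapped alignment cannot beat an ungapped one, and the ungapped model has
exactly enumerable semantics that a brute-force oracle can verify.
Every window length from ⌈0.95·L⌉ to L anchored at either spacer end is
scored at every target offset (vectorised over offsets); overlapping hits
on one strand collapse to the fewest-mismatch, then longest, then leftmost
representative.  Spacers shorter than 15 nt are rejected outright as
spurious-match prone, and the empirical false-positive rate of random
30-mers against random 50 kb targets at default thresholds is below 10⁻³
per pair.

Host linking aggregates matches of every database spacer against every
candidate phage; each spacer carries the host lineage of its source
genome.  A phage is **co-targeted** when its supporting spacers span at
least two lineages including at least one SGA and one non-SGA lineage.
`shared_spacers` checks two spacer inventories for full-length identical
sequences in either orientation (100% identity, 100% coverage) — an empty
result supports ruling out horizontal transfer of arrays between genomes
as the explanation for co-targeting.

## Pipeline and reporting

`run_pipeline` chains the stages on FASTA/TSV inputs and writes plain-text
reports (GFF3, FASTA, TSV, JSON manifest).  Outputs are a pure function of
inputs and configuration: no timestamps, stable orderings everywhere, and
identical runs are byte-identical.  Prevalence percentages are rounded
half-up to one decimal (16/44 prints as 36.4; sources that truncate would
print 36.3 — the difference is within the reporting tolerance).  Stage
warnings (short spacers, unknown cas labels, imported spacer counts) are
collected into the manifest.

## Synthetic data

The generator produces single linear contigs with planted, fully recorded
ground truth; the same spec (including its seed) yields byte-identical
output.

**Composition.**  Genes alternate with random intergenic sequence.  Amino
acids are drawn from a typical prokaryotic frequency table (a usage hook
accepts overrides), and the codon for each amino acid is chosen with an
AT-rich bias (weight 4.0 per A/T base); intergenic sequence is sampled at
70% AT.  This models the strong AT richness of the organisms and phages in
question, and it is load-bearing: under a maximal-ORF caller, AT-rich
sequence has high stop-codon density in non-coding frames, which is what
keeps spurious ORF coverage low and lets the Δd contrast emerge — with
uniform composition, random DNA is itself ~87% covered by code-11 ORFs and
the contrast collapses.  Under code 25, each glycine is written as TGA
with probability `tga_gly_fraction` (0.3 in the standard panels, ~2% of
codons); this parameter is forced to 0 under code 11, so code-11 genomes
contain no in-frame TGA within genes by construction.

**Parameters.**  Defaults: gene fraction 0.90 (phage-like coding
density), mean gene length 900 nt, stop codons drawn from the genome's
code, and a TAA/TAG backup stop planted in-frame within 10 codons
downstream of each gene with probability 0.9 — the terminus arrangement
the terminus analysis detects.  At these settings 30 kb genomes measure
Δd ≈ 13–22 points when written in code 25 (tga_gly_fraction 0.3) and
Δd ≈ 1–4 points when written in code 11, mirroring a bimodal
density-change histogram with a wide margin on both sides of the 10-point
threshold.

**Planted elements.**  CRISPR arrays (identical repeat copies, default
30 nt, around unique random spacers, default five of 32 nt) and labelled
cas operons are spliced between genes with 30 nt guards.  The guards are
adjusted so the columns flanking the repeat copies are never unanimous:
otherwise the repeat boundary would be genuinely ambiguous and any
detector would extend one column into the spacers.  Phages plant
protospacers copied from host array spacers, with scheduled substitutions
placed at *interior* spacer positions — outside the terminal margin that
coverage-based matching may truncate — so the scheduled mismatch count is
exactly the effective one and a 2-mismatch plant can never be rescued by
an end-truncated window.

**The small world.**  `make_small_world` builds the canonical test
scenario: six host genomes (two Saccharibacteria, two Gracilibacteria,
one Absconditabacteria, one Firmicutes outgroup) covering all five cas
subtypes plus one incomplete system, each with one five-spacer array; and
twelve 30 kb phages covering exact and 1-mismatch protospacers (linkable),
2- and 3-mismatch protospacers (must not link), two co-targeted phages and
two decoys, with genetic codes split between 11 and 25.

**What the synthetic data does not emulate** — and hence what passing
tests do and do not show about real data: phage genome architecture (gene
order, modules), real codon usage beyond composition bias, repeat-copy
degeneracy within arrays (planted copies are identical; the detector's
identity thresholds are exercised separately), misbinning and
contamination, read-level artefacts, and partially degraded protospacers
with indels.  Results on generated data validate the machinery — exact
recovery of planted truth under the stated conditions — not database-scale
discovery performance.

## Numerical choices and limitations

- Ties everywhere resolve deterministically (leftmost, then lexicographic);
  no stage depends on iteration order of unordered containers.
- Array detection assumes an exact shared 8-mer across repeat copies; very
  degenerate repeats (< ~90% identity) can fall below seeding or truncate
  at the first disagreeing column under the default all-agree extension.
  Lowering `agree_frac` trades boundary exactness for tolerance.
- Spacer pairwise identity uses a left-aligned match count over the longer
  length — crude, but only used to flag near-duplicate spacers inside one
  array.
- The maximal-ORF density is an upper bound on gene-caller density; its
  absolute values are not comparable to trained-caller densities, only the
  code-11/code-25 *difference* is the signal.
- Problem sizes in the test and acceptance panels (30–35 kb genomes, 50
  phages, 1,000-pair oracle sweeps) were chosen so the full suite settles
  in a few minutes on one core while keeping multi-sigma margins on every
  statistical assertion.
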