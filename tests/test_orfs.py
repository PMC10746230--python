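"""ORF calling, coding density, the dual-code classifier and termini."""

import pytest

from crisphage.genetic_codes import CODE_11, CODE_25, reverse_complement
from crisphage.orfs import (
    EmptyInputError,
    analyze_termini,
    coding_density,
    find_orfs,
    interval_union_length,
    profile_code,
)
from crisphage.synthetic import GenomeSpec, generate_genome

from .conftest import random_dna

STARTS = {"ATG", "GTG", "TTG"}


def orf_oracle(seq, code, min_orf_len):
    """Exhaustive per-frame enumeration: every stop partitions a frame into
    segments; the maximal ORF of a segment runs from its first start codon
    to the segment's stop (or edge).  Written independently of the caller."""
    results = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            stops = [i for i in codon_starts if s[i : i + 3] in code.stops]
            bounds = []
            prev = frame
            for stp in stops:
                bounds.append((prev, stp, True))
                prev = stp + 3
            if codon_starts:
                bounds.append((prev, codon_starts[-1] + 3, False))
            for seg_start, seg_end, stopped in bounds:
                starts = [
                    i
                    for i in range(seg_start, seg_end, 3)
                    if s[i : i + 3] in STARTS
                ]
                if not starts:
                    continue
                a = starts[0]
                b = seg_end + 3 if stopped else seg_end
                if b - a < min_orf_len:
                    continue
                if strand == "+":
                    results.add((a, b, strand, stopped))
                else:
                    results.add((n - b, n - a, strand, stopped))
    return results


class TestFindOrfs:
    def test_no_start_codon_no_orfs(self):
        assert find_orfs("CCC" * 40, CODE_11, min_orf_len=90) == []

    def test_reassigned_tga_extends_orf(self):
        seq = "ATGAAATGATAA"
        o11 = [o for o in find_orfs(seq, CODE_11, 6) if o.frame == 0 and o.strand == "+"]
        o25 = [o for o in find_orfs(seq, CODE_25, 6) if o.frame == 0 and o.strand == "+"]
        assert (o11[0].start, o11[0].end) == (0, 9)  # stops at TGA
        assert (o25[0].start, o25[0].end) == (0, 12)  # reads through to TAA
        assert o25[0].inframe_tga == (6,)
        assert o11[0].inframe_tga == ()

    def test_empty_sequence_raises(self):
        with pytest.raises(EmptyInputError):
            find_orfs("", CODE_11)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(25):
            seq = random_dna(rng, 2000, at=0.6)
            for code in (CODE_11, CODE_25):
                got = {
                    (o.start, o.end, o.strand, o.has_terminal_stop)
                    for o in find_orfs(seq, code, min_orf_len=90)
                }
                assert got == orf_oracle(seq, code, 90)

    def test_ambiguous_codon_breaks_orf(self):
        # ATG then NNN: the open frame is aborted, no ORF reported
        seq = "ATGAAANNNAAATAA"
        orfs = [o for o in find_orfs(seq, CODE_11, 6) if o.strand == "+" and o.frame == 0]
        assert all(o.start != 0 for o in orfs)


class TestInvariants:
    def test_code11_orf_contained_in_exactly_one_code25_orf(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 1500, at=0.6)
            o25 = find_orfs(seq, CODE_25, 90)
            for o in find_orfs(seq, CODE_11, 90):
                containers = [
                    p
                    for p in o25
                    if p.strand == o.strand
                    and p.frame == o.frame
                    and p.start <= o.start
                    and o.end <= p.end
                ]
                assert len(containers) == 1

    def test_reverse_complement_closure(self, rng):
        seq = random_dna(rng, 1200, at=0.6)
        n = len(seq)
        fwd = find_orfs(seq, CODE_11, 90)
        rev = find_orfs(reverse_complement(seq), CODE_11, 90)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (n - o.end, n - o.start, flip[o.strand], o.has_terminal_stop)
            for o in rev
        }
        assert {(o.start, o.end, o.strand, o.has_terminal_stop) for o in fwd} == mirrored

    def test_density_monotone_d25_ge_d11(self, rng):
        for _ in range(40):
            seq = random_dna(rng, 600, at=rng.uniform(0.4, 0.75))
            assert coding_density(seq, CODE_25) >= coding_density(seq, CODE_11)

    def test_planted_gene_bases_recovered(self):
        """>=95% of planted gene bases lie inside ORFs called under the
        planted code (generator/caller sensitivity)."""
        for code_id, tga in ((11, 0.0), (25, 0.3)):
            spec = GenomeSpec("g", 30000, code_id=code_id, tga_gly_fraction=tga, seed=5)
            seq, truth = generate_genome(spec)
            code = CODE_25 if code_id == 25 else CODE_11
            orfs = find_orfs(seq, code, 90)
            mask = bytearray(len(seq))
            for o in orfs:
                for i in range(o.start, o.end):
                    mask[i] = 1
            gene_bases = covered = 0
            for s, e, _ in truth.genes:
                gene_bases += e - s
                covered += sum(mask[s:e])
            assert covered / gene_bases >= 0.95


class TestCodingDensity:
    def test_no_orfs_zero_density(self):
        assert coding_density("CCC" * 40, CODE_11) == 0.0

    def test_full_coverage_single_orf(self):
        seq = "ATG" + "AAA" * 30 + "TAA"
        assert coding_density(seq, CODE_11, min_orf_len=90) == 1.0

    def test_union_equals_per_base_mask(self, rng):
        seq = random_dna(rng, 3000, at=0.65)
        orfs = find_orfs(seq, CODE_11, 90)
        mask = bytearray(len(seq))
        for o in orfs:
            for i in range(o.start, o.end):
                mask[i] = 1
        assert coding_density(seq, CODE_11) == sum(mask) / len(seq)

    def test_interval_union_counts_overlap_once(self):
        assert interval_union_length([(0, 100), (50, 150)]) == 150
        assert interval_union_length([]) == 0


class TestProfileCode:
    def test_code25_genome_called_code25(self):
        seq, _ = generate_genome(
            GenomeSpec("g", 30000, code_id=25, tga_gly_fraction=0.3, seed=11)
        )
        prof = profile_code(seq)
        assert prof.call == "code25"
        assert prof.delta >= 10

    def test_code11_genome_called_compatible(self):
        seq, _ = generate_genome(GenomeSpec("g", 30000, code_id=11, seed=11))
        prof = profile_code(seq)
        assert prof.call == "code11_compatible"
        assert abs(prof.delta) < 10

    def test_short_sequence_not_evaluated(self, rng):
        seq = random_dna(rng, 15000)
        assert profile_code(seq).call == "not_evaluated"

    def test_densities_ordered(self, rng):
        prof = profile_code(random_dna(rng, 21001))
        assert 0.0 <= prof.d11 <= prof.d25 <= 1.0


class TestTermini:
    def _orf_ending(self, terminal, downstream):
        """Build a sequence with one long ORF ending in `terminal`,
        followed by `downstream`."""
        seq = "ATG" + "GCT" * 40 + terminal + downstream
        code = CODE_11 if terminal == "TGA" else CODE_25
        orfs = [o for o in find_orfs(seq, code, 90) if o.strand == "+" and o.start == 0]
        assert orfs, "fixture must contain the constructed ORF"
        return seq, orfs

    def test_shared_stop_is_viable(self):
        seq, orfs = self._orf_ending("TAA", "CCCCCC")
        rep = analyze_termini(seq, orfs)[0]
        assert rep.terminal_stop_codon == "TAA"
        assert rep.code11_viable_terminus
        assert rep.code11_translatable  # no in-frame TGA either

    def test_tga_terminus_with_backup_tag(self):
        # TAG two codons downstream of the TGA stop, window 10
        seq, orfs = self._orf_ending("TGA", "CCC" + "TAG" + "CCC")
        rep = analyze_termini(seq, orfs, window=10)[0]
        assert rep.terminal_stop_codon == "TGA"
        assert ("TAG", 2) in rep.backup_stops
        assert rep.code11_viable_terminus

    def test_tga_terminus_without_backup_not_viable(self):
        seq, orfs = self._orf_ending("TGA", "CCC" * 12)
        rep = analyze_termini(seq, orfs, window=10)[0]
        assert rep.terminal_stop_codon == "TGA"
        assert not rep.code11_viable_terminus

    def test_edge_orf_reported_as_none(self):
        seq = "ATG" + "GCT" * 40  # runs off the contig edge
        orfs = find_orfs(seq, CODE_11, 90)
        rep = analyze_termini(seq, orfs)[0]
        assert rep.terminal_stop_codon == "none"
        assert not rep.code11_viable_terminus

    def test_out_of_bounds_orf_raises(self):
        seq, orfs = self._orf_ending("TAA", "")
        with pytest.raises(IndexError):
            analyze_termini(seq[:50], orfs)

    def test_generator_backup_stops_make_code11_genes_viable(self):
        """Code-11 genomes plant backup stops after every gene: each planted
        TGA-terminated gene must test dual-code viable."""
        seq, truth = generate_genome(
            GenomeSpec("g", 30000, code_id=11, backup_stop_prob=1.0, seed=3)
        )
        plus_ends = {e for s, e, st in truth.genes if st == "+"}
        minus_starts = {s for s, e, st in truth.genes if st == "-"}
        orfs = [
            o for o in find_orfs(seq, CODE_11, 90)
            if (o.strand == "+" and o.end in plus_ends)
            or (o.strand == "-" and o.start in minus_starts)
        ]
        reports = analyze_termini(seq, orfs, window=10)
        tga_reports = [r for r in reports if r.terminal_stop_codon == "TGA"]
        assert tga_reports, "expect some TGA-terminated genes"
        assert all(r.code11_viable_terminus for r in tga_reports)
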