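"""Spacer-protospacer matching semantics, oracle checks and host linking."""

import math

import pytest

from crisphage.arrays import SpacerDb, SpacerRecord
from crisphage.genetic_codes import reverse_complement
from crisphage.matching import (
    HostLink,
    SpacerHit,
    find_cotargeted,
    link_hosts,
    match_spacer,
    shared_spacers,
)

from .conftest import random_dna


def oracle_match(spacer, target, min_coverage=0.95, max_mismatch=1):
    """Brute force: every (strand, end-anchored window, offset) is scored by
    direct character comparison; overlapping same-strand candidates collapse
    to the (fewest mismatches, longest, leftmost) representative."""
    L = len(spacer)
    lmin = math.ceil(min_coverage * L)
    raw = []
    for strand, pat in (("+", spacer), ("-", reverse_complement(spacer))):
        windows = set()
        for lp in range(lmin, L + 1):
            windows.add(pat[:lp])
            windows.add(pat[len(pat) - lp:])
        for w in windows:
            for i in range(len(target) - len(w) + 1):
                mm = sum(a != b for a, b in zip(w, target[i : i + len(w)]))
                if mm <= max_mismatch:
                    raw.append((strand, i, i + len(w), len(w), mm))
    best = []
    for strand in "+-":
        cands = sorted(r for r in raw if r[0] == strand)
        clusters = []
        for c in cands:
            if clusters and c[1] < max(x[2] for x in clusters[-1]):
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cl in clusters:
            best.append(min(cl, key=lambda r: (r[4], -r[3], r[1])))
    return sorted(best, key=lambda r: (r[1], r[2], r[0]))


def as_tuples(hits):
    return sorted(
        (h.strand, h.start, h.end, h.matched_len, h.mismatches) for h in hits
    )


class TestMatchSpacer:
    def test_exact_planted_match(self, rng):
        spacer = random_dna(rng, 30)
        target = random_dna(rng, 500) + spacer + random_dna(rng, 500)
        (hit,) = match_spacer(spacer, target)
        assert (hit.start, hit.end) == (500, 530)
        assert hit.mismatches == 0
        assert hit.coverage == 1.0
        assert hit.strand == "+"

    def test_two_interior_mismatches_rejected(self, rng):
        spacer = random_dna(rng, 30)
        mutated = list(spacer)
        for pos in (5, 20):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        target = random_dna(rng, 300) + "".join(mutated) + random_dna(rng, 300)
        assert match_spacer(spacer, target) == []

    def test_minus_strand_reported_on_forward_coords(self, rng):
        spacer = random_dna(rng, 30)
        target = random_dna(rng, 200) + reverse_complement(spacer) + random_dna(rng, 200)
        (hit,) = match_spacer(spacer, target)
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (200, 230)

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            match_spacer("ACGTACGTACGT", "ACGT" * 50)

    def test_equals_bruteforce_oracle(self, rng):
        for _ in range(150):
            L = int(rng.integers(20, 41))
            spacer = random_dna(rng, L)
            target = random_dna(rng, 150)
            # plant a perturbed copy half the time to exercise near-misses
            if rng.random() < 0.5:
                copy = list(spacer)
                for pos in rng.choice(L, size=int(rng.integers(0, 3)), replace=False):
                    copy[pos] = "ACGT"[int(rng.integers(0, 4))]
                i = int(rng.integers(0, len(target) - L))
                target = target[:i] + "".join(copy) + target[i + L:]
            got = as_tuples(match_spacer(spacer, target))
            want = [
                (s, a, b, ln, mm)
                for s, a, b, ln, mm in oracle_match(spacer, target)
            ]
            assert got == sorted(want)

    def test_strand_symmetry(self, rng):
        spacer = random_dna(rng, 28)
        target = random_dna(rng, 300) + spacer + random_dna(rng, 100)
        direct = as_tuples(match_spacer(spacer, target))
        flipped = as_tuples(match_spacer(reverse_complement(spacer), target))
        swap = {"+": "-", "-": "+"}
        assert direct == sorted(
            (swap[s], a, b, ln, mm) for s, a, b, ln, mm in flipped
        )

    def test_relaxing_thresholds_never_removes_hits(self, rng):
        spacer = random_dna(rng, 30)
        mutated = list(spacer)
        mutated[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[10]]
        target = random_dna(rng, 200) + "".join(mutated) + random_dna(rng, 200)
        strict = {(h.start, h.strand) for h in match_spacer(spacer, target, 0.95, 0)}
        loose = {(h.start, h.strand) for h in match_spacer(spacer, target, 0.95, 1)}
        loosest = {(h.start, h.strand) for h in match_spacer(spacer, target, 0.90, 2)}
        assert strict <= loose <= loosest

    def test_false_positive_rate_below_1e3(self, rng):
        hits = 0
        n_pairs = 200
        for _ in range(n_pairs):
            hits += len(match_spacer(random_dna(rng, 30), random_dna(rng, 50000)))
        assert hits / n_pairs < 1e-3


def _db(entries):
    db = SpacerDb()
    for sid, src, seq in entries:
        db.add(SpacerRecord(sid, src, 0, 0, seq))
    return db


class TestLinking:
    def test_single_spacer_single_target(self, rng):
        sp = random_dna(rng, 30)
        targets = {
            "t1": random_dna(rng, 400) + sp + random_dna(rng, 400),
            "t2": random_dna(rng, 800),
            "t3": random_dna(rng, 800),
        }
        links = link_hosts(_db([("s1", "g1", sp)]), targets, {"g1": "Gracilibacteria"})
        assert [l.target_id for l in links] == ["t1"]
        assert links[0].host_groups == ("Gracilibacteria",)

    def test_empty_db_no_links(self, rng):
        assert link_hosts(_db([]), {"t": random_dna(rng, 500)}, {}) == []

    def test_missing_host_group_raises(self, rng):
        sp = random_dna(rng, 30)
        with pytest.raises(KeyError, match="gX"):
            link_hosts(_db([("s1", "gX", sp)]), {"t": sp + random_dna(rng, 100)}, {})


class TestCotargeting:
    @staticmethod
    def _link(target, groups):
        hits = tuple(
            SpacerHit(f"s{i}", target, 0, 30, "+", 30, 0, 1.0)
            for i in range(len(groups))
        )
        return HostLink(target, hits, tuple(groups))

    def test_sga_plus_non_sga_is_cotargeted(self):
        links = [self._link("p1", ["Gracilibacteria", "Firmicutes"])]
        assert [t for t, _ in find_cotargeted(links)] == ["p1"]

    def test_multiple_sga_genomes_same_group_not_cotargeted(self):
        links = [self._link("p1", ["Saccharibacteria", "Saccharibacteria"])]
        assert find_cotargeted(links) == []

    def test_two_sga_groups_without_non_sga_not_cotargeted(self):
        links = [self._link("p1", ["Saccharibacteria", "Gracilibacteria"])]
        assert find_cotargeted(links) == []


class TestSharedSpacers:
    def test_disjoint_inventories(self):
        assert shared_spacers(["ACGTACGTACGTACGTACGT"], ["TTTTTTTTTTGGGGGGGGGG"]) == []

    def test_identical_spacer_shared(self):
        s = "ACGTACGTACGTACGTACGT"
        assert shared_spacers([s], [s]) == [(s, "+")]

    def test_reverse_complement_flagged(self):
        s = "AAAACCCCGGGGTTTTACGT"
        assert shared_spacers([s], [reverse_complement(s)]) == [(s, "-")]
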