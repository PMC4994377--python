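"""Global alignment statistics and duplication / homoeolog calling."""

import functools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genefam import align_dup
from genefam.align_dup import call_duplications, global_align
from genefam.genome_map import parse_locus

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5


def brute_force_affine_score(a: str, b: str) -> float:
    """Exhaustive three-state dynamic program (reference oracle).

    A gap of length k costs open + (k-1)*extend, matching the aligner's
    convention that the opening position already pays the open score.
    """

    @functools.lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if j < len(b):  # gap in a
            cost = GAP_EXTEND if state == "GA" else GAP_OPEN
            best = max(best, -cost + rec(i, j + 1, "GA"))
        if i < len(a):  # gap in b
            cost = GAP_EXTEND if state == "GB" else GAP_OPEN
            best = max(best, -cost + rec(i + 1, j, "GB"))
        return best

    return rec(0, 0, "M")


def test_identical_sequences_align_perfectly():
    r = global_align("ACDEFG", "ACDEFG")
    assert r.identity_pct == 100.0 and r.coverage_pct == 100.0


def test_single_substitution_identity():
    r = global_align("ACDEFG", "ACDKFG")
    assert r.identity_pct == pytest.approx(100 * 5 / 6)
    assert r.coverage_pct == 100.0


def test_coverage_uses_longer_sequence():
    r = global_align("AAAA", "AA")
    assert r.coverage_pct <= 50.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACD")


def test_score_matches_brute_force_oracle_on_short_pairs():
    rng = np.random.default_rng(11)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(40):
        a = "".join(rng.choice(aa, size=rng.integers(3, 13)))
        b = "".join(rng.choice(aa, size=rng.integers(3, 13)))
        got = global_align(a, b).score
        assert got == pytest.approx(brute_force_affine_score(a, b))


def test_alignment_statistics_are_symmetric():
    rng = np.random.default_rng(5)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        a = "".join(rng.choice(aa, size=30))
        b = "".join(rng.choice(aa, size=25))
        r1, r2 = global_align(a, b), global_align(b, a)
        assert r1.identity_pct == pytest.approx(r2.identity_pct)
        assert r1.coverage_pct == pytest.approx(r2.coverage_pct)
        assert r1.score == pytest.approx(r2.score)


def _mutate(seq, n_sub, rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    chars = list(seq)
    for i in rng.choice(len(chars), size=n_sub, replace=False):
        chars[i] = aa[(aa.index(chars[i]) + 1) % 20]
    return "".join(chars)


def test_planted_pair_above_threshold_reported_and_70pct_absent():
    rng = np.random.default_rng(3)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aa, size=200))
    seqs = {
        "hi_a": base,
        "hi_b": _mutate(base, 20, rng),  # ~90 % identity
        "lo_a": "".join(rng.choice(aa, size=200)),
    }
    seqs["lo_b"] = _mutate(seqs["lo_a"], 60, rng)  # ~70 % identity
    loci = {
        "hi_a": parse_locus("hi_a", "1A:1000000-1000600"),
        "hi_b": parse_locus("hi_b", "1B:1000000-1000600"),
        "lo_a": parse_locus("lo_a", "2A:1000000-1000600"),
        "lo_b": parse_locus("lo_b", "2D:1000000-1000600"),
    }
    pairs = call_duplications(seqs, loci)
    found = {(p.id_a, p.id_b) for p in pairs}
    assert ("hi_a", "hi_b") in found
    assert all("lo_a" not in pair for pair in found)


def test_three_tandem_copies_collapse_to_one_event():
    rng = np.random.default_rng(8)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aa, size=150))
    seqs = {f"t{i}": _mutate(base, 8, rng) for i in range(3)}
    loci = {
        "t0": parse_locus("t0", "4A:100000-100500"),
        "t1": parse_locus("t1", "4A:130000-130500"),
        "t2": parse_locus("t2", "4A:160000-160500"),
    }
    pairs = call_duplications(seqs, loci, tandem_window=100_000)
    assert len(pairs) == 1
    assert pairs[0].kind == "intra_chromosome"
    assert len(pairs[0].collapsed_from) == 2


def test_missing_locus_rejected():
    with pytest.raises(ValueError, match="without a locus"):
        call_duplications({"a": "ACDE"}, {})


def test_duplication_calling_is_permutation_invariant():
    rng = np.random.default_rng(21)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aa, size=120))
    seqs = {f"g{i}": _mutate(base, 10, rng) for i in range(4)}
    loci = {
        g: parse_locus(g, f"{1 + i % 7}{'ABD'[i % 3]}:1000000-1000360")
        for i, g in enumerate(seqs)
    }
    p1 = call_duplications(seqs, loci)
    reordered = dict(reversed(list(seqs.items())))
    p2 = call_duplications(reordered, loci)
    assert [(p.id_a, p.id_b, p.kind) for p in p1] == [
        (p.id_a, p.id_b, p.kind) for p in p2
    ]


def test_planted_structure_recovered_exactly(layout_recovery):
    """Triads, two-subgenome pairs and tandem collapses from the synthetic
    genome layout are recovered exactly."""
    spec, layout, pairs, groups = layout_recovery
    truth = layout.truth

    triads = [g for g in groups if g.is_triad]
    two_sub = [g for g in groups if g.n_subgenomes == 2]
    assert len(triads) == spec.n_triads
    assert len(two_sub) == spec.n_pairs

    # membership matches the planted units exactly
    planted_units = {
        unit: set(sub.gene_id)
        for unit, sub in truth[truth.role.isin(["triad", "pair"])].groupby("unit")
    }
    recovered_units = {
        frozenset(gene for genes in g.members.values() for gene in genes)
        for g in groups
    }
    assert recovered_units == {frozenset(v) for v in planted_units.values()}

    # each tandem cluster collapses to exactly one intra-chromosome event
    tandem_events = [
        p for p in pairs if p.kind == "intra_chromosome" and p.collapsed_from
    ]
    assert len(tandem_events) == spec.n_tandem_clusters

    # singletons never appear in any pair
    singles = set(truth[truth.role == "singleton"].gene_id)
    for p in pairs:
        assert p.id_a not in singles and p.id_b not in singles
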