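"""Nei-Gojobori counting, Ks matrices, dating, NJ trees and bootstrap."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from amplicony import evolution, simulate
from amplicony.evolution import (
    CodonAlignment,
    DistanceMatrix,
    bootstrap_support,
    estimate_duplication_age,
    jc_nucleotide_distance,
    ks_matrix,
    ks_summary,
    ng_pair,
    nj_tree,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return "*" if codon in STOPS else str(Seq(codon).translate())


def oracle_ng(row1, row2):
    """Independent Nei-Gojobori oracle: explicit enumeration throughout.

    Site fractions from the genetic code position by position; difference
    counts averaged over all orderings of the differing positions, with
    stop-visiting pathways removed when any stop-free pathway exists.
    """
    S = N = Sd = Nd = 0.0
    for k in range(0, len(row1), 3):
        c1, c2 = row1[k : k + 3], row2[k : k + 3]
        if any(ch not in BASES for ch in c1 + c2):
            continue
        if c1 in STOPS or c2 in STOPS:
            continue
        for c in (c1, c2):
            syn = 0
            for pos in range(3):
                for b in BASES:
                    if b != c[pos]:
                        mut = c[:pos] + b + c[pos + 1 :]
                        if _aa(mut) == _aa(c):
                            syn += 1
            S += syn / 6.0          # average of the two sequences
            N += (9 - syn) / 6.0
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if not diffs:
            continue
        paths = []
        for order in itertools.permutations(diffs):
            cur, sd, nd, hits_stop = c1, 0, 0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt in STOPS and nxt != c2:
                    hits_stop = True
                if _aa(nxt) == _aa(cur) and nxt not in STOPS:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd, hits_stop))
        ok = [(s, n) for s, n, h in paths if not h] or \
             [(s, n) for s, n, _ in paths]
        Sd += sum(s for s, _ in ok) / len(ok)
        Nd += sum(n for _, n in ok) / len(ok)
    return S, N, Sd, Nd


def random_codon_row(rng, n_codons):
    row = []
    while len(row) < n_codons:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOPS:
            row.append(codon)
    return "".join(row)


class TestNgPair:
    def test_identical_sequences(self):
        row = simulate.random_cds(100, 0)
        r = ng_pair(row, row)
        assert r.Sd == 0 and r.Nd == 0 and r.dS == 0 and r.dN == 0

    def test_single_codon_hand_count(self):
        # TTT vs TTC: position 3 of TTT has 1 synonymous of 3 one-step
        # changes, so S = 1/3 per sequence; the single difference is
        # synonymous, giving ps = 3 and an undefined (saturated) dS
        r = ng_pair("TTT", "TTC")
        assert r.S == pytest.approx(1 / 3)
        assert r.N == pytest.approx(8 / 3)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.ps == pytest.approx(3.0)
        assert r.dS is None

    def test_sites_sum_to_three_per_codon(self, rng):
        for _ in range(20):
            a = random_codon_row(rng, 30)
            b = random_codon_row(rng, 30)
            r = ng_pair(a, b)
            assert r.S + r.N == pytest.approx(3 * r.codons_compared)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a = random_codon_row(rng, 25)
            b = random_codon_row(rng, 25)
            r1, r2 = ng_pair(a, b), ng_pair(b, a)
            assert (r1.S, r1.N, r1.Sd, r1.Nd) == \
                pytest.approx((r2.S, r2.N, r2.Sd, r2.Nd))

    def test_matches_exhaustive_pathway_oracle(self, rng):
        for _ in range(200):
            a = random_codon_row(rng, 30)
            # correlated second row so difference counts are non-trivial
            b = simulate.mutate_jc(a, float(rng.uniform(0, 0.4)),
                                   int(rng.integers(2**31)))
            r = ng_pair(a, b)
            S, N, Sd, Nd = oracle_ng(a, b)
            assert (r.S, r.N, r.Sd, r.Nd) == pytest.approx((S, N, Sd, Nd))

    def test_pairwise_deletion_of_gap_and_n_codons(self):
        r = ng_pair("ATG---AACNNT", "ATGAAAAACAAT")
        assert r.codons_compared == 2  # codons 1 and 3 only

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng_pair("ATGAAA", "ATG")


class TestKsMatrix:
    def test_identical_rows_all_zero(self):
        row = simulate.random_cds(50, 1)
        m = ks_matrix(CodonAlignment(["a", "b", "c"], [row] * 3))
        assert np.allclose(m.values, 0.0)

    def test_disjoint_gap_pair_undefined(self):
        a = "ATGAAA" + "------"
        b = "------" + "ATGAAA"
        c = "ATGAAA" + "ATGAAA"
        m = ks_matrix(CodonAlignment(["a", "b", "c"], [a, b, c]))
        assert np.isnan(m.values[0, 1])
        assert not np.isnan(m.values[0, 2])

    def test_recovers_simulated_divergence(self):
        # true divergence 0.15 substitutions/site between the rows
        ests = []
        for s in range(20):
            base = simulate.random_cds(1600, 200 + s)
            r1 = simulate.mutate_jc(base, 0.075, 2 * s)
            r2 = simulate.mutate_jc(base, 0.075, 2 * s + 1)
            ests.append(ng_pair(r1, r2).dS)
        assert abs(np.mean(ests) - 0.15) < 0.015

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            ks_matrix(CodonAlignment(["a"], ["ATG"]))

    def test_summary_most_distant_taxon(self):
        values = np.array([
            [0.0, 0.01, 0.30],
            [0.01, 0.0, 0.29],
            [0.30, 0.29, 0.0],
        ])
        s = ks_summary(DistanceMatrix(["a", "b", "c"], values))
        assert s["most_distant_taxon"] == "c"
        assert s["max_ks"] == pytest.approx(0.30)


class TestDuplicationAge:
    def test_worked_example(self):
        age = estimate_duplication_age(0.0443, 0.1517, 19.6)
        assert age == pytest.approx(5.7238, abs=1e-3)
        assert round(age, 1) == 5.7

    def test_zero_divergence_zero_age(self):
        assert estimate_duplication_age(0.0, 0.2, 19.6) == 0.0

    def test_locus_as_old_as_split(self):
        assert estimate_duplication_age(0.13, 0.13, 19.6) \
            == pytest.approx(19.6)

    def test_linear_in_each_argument(self):
        base = estimate_duplication_age(0.05, 0.2, 10.0)
        assert estimate_duplication_age(0.10, 0.2, 10.0) \
            == pytest.approx(2 * base)
        assert estimate_duplication_age(0.05, 0.4, 10.0) \
            == pytest.approx(base / 2)
        assert estimate_duplication_age(0.05, 0.2, 20.0) \
            == pytest.approx(2 * base)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            estimate_duplication_age(0.1, 0.0, 19.6)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths; returns the
    pairwise path-length matrix and the canonical bipartition set."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    all_taxa = frozenset(taxa)
    dist = {t: {t: 0.0} for t in taxa}
    # start from leaves, join random pairs of clusters
    clusters = [[t] for t in taxa]
    leaf_depth = {t: float(rng.uniform(0.1, 1.0)) for t in taxa}
    D = np.zeros((n_taxa, n_taxa))
    idx = {t: i for i, t in enumerate(taxa)}
    depths = {frozenset([t]): {t: float(rng.uniform(0.1, 1.0))} for t in taxa}
    bipartitions = set()
    clusters = [frozenset([t]) for t in taxa]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        for x in a:
            for y in b:
                D[idx[x], idx[y]] = D[idx[y], idx[x]] = \
                    depths[a][x] + depths[b][y]
        merged = a | b
        if len(clusters) > 2:
            bl = float(rng.uniform(0.1, 1.0))
        else:
            bl = 0.0
        depths[merged] = {
            x: depths[a if x in a else b][x] + bl for x in merged
        }
        if 1 < len(merged) < n_taxa - 1:
            side = merged
            other = all_taxa - side
            canon = side if len(side) < len(other) else (
                other if len(other) < len(side)
                else min(side, other, key=lambda s: tuple(sorted(s)))
            )
            bipartitions.add(canon)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return taxa, D, bipartitions


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances additive on topology AB|CD
        taxa = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(taxa, D))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        got = tree.leaf_distances()
        for i, a in enumerate(taxa):
            for j in range(i + 1, 4):
                key = (a, taxa[j]) if a < taxa[j] else (taxa[j], a)
                assert got[key] == pytest.approx(D[i, j])

    def test_three_taxa_closed_form(self):
        # leaf branch lengths a=1, b=2, c=3
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        got = tree.leaf_distances()
        assert got[("a", "b")] == pytest.approx(3)
        assert got[("a", "c")] == pytest.approx(4)
        assert got[("b", "c")] == pytest.approx(5)

    def test_zero_matrix_zero_branches(self):
        D = np.zeros((4, 4))
        tree = nj_tree(DistanceMatrix(list("abcd"), D))
        assert all(v == pytest.approx(0.0)
                   for v in tree.leaf_distances().values())

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            taxa, D, true_bps = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(taxa, D))
            assert tree.bipartitions() == true_bps
            got = tree.leaf_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((taxa[i], taxa[j])))
                    assert got[key] == pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_skbio_topology(self):
        import skbio

        rng = np.random.default_rng(5)
        taxa, D, _ = random_additive_tree(rng, 7)
        ours = nj_tree(DistanceMatrix(taxa, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=taxa))
        their_bps = set()
        all_taxa = frozenset(taxa)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                other = all_taxa - side
                canon = side if len(side) < len(other) else (
                    other if len(other) < len(side)
                    else min(side, other, key=lambda s: tuple(sorted(s)))
                )
                their_bps.add(canon)
        assert ours.bipartitions() == their_bps

    def test_undefined_entries_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(list("abc"), D))


def _two_clade_alignment(n_codons=600, tips=3, seed=5):
    base = simulate.random_cds(n_codons, 1)
    anc1 = simulate.mutate_jc(base, 0.15, 2)
    anc2 = simulate.mutate_jc(base, 0.15, 3)
    taxa, rows = [], []
    for i in range(tips):
        taxa.append(f"x{i}")
        rows.append(simulate.mutate_jc(anc1, 0.005, 10 + i))
    for i in range(tips):
        taxa.append(f"y{i}")
        rows.append(simulate.mutate_jc(anc2, 0.005, 20 + i))
    return CodonAlignment(taxa, rows)


class TestBootstrap:
    def test_single_replicate_support_is_zero_or_hundred(self):
        aln = _two_clade_alignment(n_codons=200)
        tree, _ = bootstrap_support(aln, n_reps=1, seed=0)
        sups = [n.support for n in _internal_children(tree)
                if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_same_support(self):
        aln = _two_clade_alignment(n_codons=200)
        t1, _ = bootstrap_support(aln, n_reps=20, seed=3)
        t2, _ = bootstrap_support(aln, n_reps=20, seed=3)
        assert _support_map(t1) == _support_map(t2)

    def test_strong_separation_high_support(self):
        # intra-clade dS ~ 0.01, inter-clade ~ 0.3 over 600 codons
        aln = _two_clade_alignment(n_codons=600)
        tree, log = bootstrap_support(aln, n_reps=100, seed=0)
        sep = frozenset({"x0", "x1", "x2"})
        smap = _support_map(tree)
        key = [bp for bp in smap
               if bp in (sep, frozenset({"y0", "y1", "y2"}))]
        assert key and all(smap[k] >= 95 for k in key)
        assert log["completed"] == 100


def _internal_children(tree):
    out = []

    def walk(node):
        for child, _ in node.children:
            if child.children:
                out.append(child)
            walk(child)

    walk(tree.root)
    return out


def _support_map(tree):
    all_taxa = frozenset(tree.taxa)
    out = {}
    for node in _internal_children(tree):
        side = frozenset(node.leaves())
        other = all_taxa - side
        canon = side if len(side) < len(other) else (
            other if len(other) < len(side)
            else min(side, other, key=lambda s: tuple(sorted(s)))
        )
        out[canon] = node.support
    return out


class TestJcNucleotide:
    def test_zero_for_identical(self):
        assert jc_nucleotide_distance("ACGT", "ACGT") == 0.0

    def test_pairwise_deletion(self):
        assert jc_nucleotide_distance("----", "ACGT") is None
        d = jc_nucleotide_distance("AC--", "ACGT")
        assert d == 0.0
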