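"""Codon-level divergence, duplication dating, and NJ phylogenetics.

Synonymous divergence (Ks/dS) is estimated with the Nei-Gojobori
counting method under the Jukes-Cantor multiple-hit correction.  For
each codon pair, codons containing a gap or N in either sequence are
dropped (pairwise deletion); synonymous site fractions come from the
standard genetic code (fraction of one-step changes per position that
preserve the amino acid, averaged between the two sequences); and
codons differing at several positions average the synonymous and
nonsynonymous difference counts over all minimal substitution pathways,
skipping pathways that pass through a stop codon.

Because synonymous changes are approximately neutral, Ks acts as a
molecular clock: with a calibrated species split at t Mya showing mean
interspecies Ks k_between, a within-family divergence k_within dates to
k_within / k_between x t.

Trees are built with Saitou-Nei neighbor joining on JC-corrected
distances (dS by default, plain nucleotide JC selectable) with bootstrap
support from codon-column resampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

_CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid for a codon; '*' for stops; None if ambiguous."""
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (sum over the 3 positions of
    the fraction of one-step changes that preserve the amino acid).

    Changes producing stop codons count as nonsynonymous.
    """
    aa = _aa(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal pathways.

    Pathways visiting a stop codon are excluded; if every pathway does,
    all pathways are used.
    """
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    tallies = []
    for order in itertools.permutations(diff_pos):
        current = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                through_stop = True
            if _aa(nxt) == _aa(current) and _aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            current = nxt
        tallies.append((sd, nd, through_stop))
    valid = [(s, n) for s, n, stop in tallies if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in tallies]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC correction d = -(3/4) ln(1 - 4p/3); None for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float | None
    pn: float | None
    dS: float | None
    dN: float | None
    codons_compared: int


def ng_pair(row1: str, row2: str) -> KsResult:
    """Nei-Gojobori synonymous/nonsynonymous divergence for one aligned pair.

    Rows are aligned CDS strings of equal length divisible by 3 over
    {A,C,G,T,N,-}.  Codons with a gap, an N, or a stop codon in either
    row are pairwise-deleted.
    """
    row1, row2 = row1.upper(), row2.upper()
    if len(row1) != len(row2) or len(row1) % 3 != 0:
        raise ValueError("rows must be equal length, divisible by 3")
    S = N = Sd = Nd = 0.0
    compared = 0
    for k in range(0, len(row1), 3):
        c1, c2 = row1[k : k + 3], row2[k : k + 3]
        if set(c1 + c2) - set(_BASES):
            continue  # gap/N codon: pairwise deletion
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, s2 = syn_site_fraction(c1), syn_site_fraction(c2)
        s_sites = (s1 + s2) / 2.0
        S += s_sites
        N += 3.0 - s_sites
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd
        compared += 1
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    dS = jukes_cantor(ps) if ps is not None else None
    dN = jukes_cantor(pn) if pn is not None else None
    return KsResult(S, N, Sd, Nd, ps, pn, dS, dN, compared)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    taxa: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1 or (lengths and next(iter(lengths)) % 3 != 0):
            raise ValueError("rows must share one length divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def resample_codons(self, rng: np.random.Generator) -> "CodonAlignment":
        cols = rng.integers(0, self.n_codons, size=self.n_codons)
        rows = [
            "".join(r[3 * c : 3 * c + 3] for c in cols) for r in self.rows
        ]
        return CodonAlignment(list(self.taxa), rows)


@dataclass
class DistanceMatrix:
    taxa: list
    values: np.ndarray  # NaN marks undefined entries

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("matrix must be symmetric")

    def defined(self) -> np.ndarray:
        mask = ~np.eye(len(self.taxa), dtype=bool)
        return self.values[mask & ~np.isnan(self.values)]


_IS_BASE = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _IS_BASE[_b] = True


def jc_nucleotide_distance(row1: str, row2: str) -> float | None:
    """Plain JC69 nucleotide distance with pairwise deletion of gap/N sites."""
    a = np.frombuffer(row1.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(row2.upper().encode(), dtype=np.uint8)
    keep = _IS_BASE[a] & _IS_BASE[b]
    n = int(keep.sum())
    if n == 0:
        return None
    p = float(np.sum(a[keep] != b[keep])) / n
    return jukes_cantor(p)


def ks_matrix(
    alignment: CodonAlignment, distance: str = "ds"
) -> DistanceMatrix:
    """All-pairs distance matrix (dS by default, 'jc' for nucleotide JC)."""
    n = len(alignment.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if distance == "ds":
                d = ng_pair(alignment.rows[i], alignment.rows[j]).dS
            elif distance == "jc":
                d = jc_nucleotide_distance(alignment.rows[i],
                                           alignment.rows[j])
            else:
                raise ValueError(f"unknown distance {distance!r}")
            values[i, j] = values[j, i] = np.nan if d is None else d
    return DistanceMatrix(list(alignment.taxa), values)


def ks_summary(matrix: DistanceMatrix) -> dict:
    """Mean/max pairwise Ks and the most distant taxon.

    The most distant taxon maximises, over taxa, that taxon's maximum
    pairwise Ks to all others.
    """
    vals = matrix.values
    defined = matrix.defined()
    off = np.where(np.eye(len(matrix.taxa), dtype=bool), np.nan, vals)
    per_taxon_max = np.nanmax(off, axis=1)
    # both endpoints of the maximal pair tie on the max; the outlier is
    # the one further from everything else on average
    per_taxon_mean = np.nanmean(off, axis=1)
    best = np.nanmax(per_taxon_max)
    tied = np.flatnonzero(per_taxon_max >= best - 1e-12)
    most_distant = int(tied[np.argmax(per_taxon_mean[tied])])
    return {
        "mean_ks": float(np.mean(defined)) if defined.size else math.nan,
        "max_ks": float(np.max(defined)) if defined.size else math.nan,
        "most_distant_taxon": matrix.taxa[most_distant],
        "most_distant_max_ks": float(per_taxon_max[most_distant]),
    }


# ---------------------------------------------------------------------------
# Duplication dating
# ---------------------------------------------------------------------------

@dataclass
class CalibrationParams:
    max_intrafamily_ks: float
    interspecies_ks_mean: float
    t_split: float = 19.6


def estimate_duplication_age(
    max_intrafamily_ks: float,
    interspecies_ks_mean: float,
    t_split: float = 19.6,
) -> float:
    """Date the oldest duplication by the Ks ratio against a calibrated split.

    age = max_intrafamily_ks / interspecies_ks_mean x t_split (Mya).
    """
    if interspecies_ks_mean <= 0:
        raise ValueError("interspecies Ks mean must be positive")
    if max_intrafamily_ks < 0 or t_split <= 0:
        raise ValueError("Ks values must be >= 0 and t_split positive")
    return max_intrafamily_ks / interspecies_ks_mean * t_split


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch length)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode
    taxa: list
    clamped_branches: int = 0

    def newick(self) -> str:
        return _newick(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal bipartitions (smaller side, ties lexicographic)."""
        all_taxa = frozenset(self.taxa)
        out = set()
        for node in _iter_nodes(self.root):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(_canonical(side, all_taxa))
        return out

    def leaf_distances(self) -> dict:
        """Path lengths between all leaf pairs (additivity checks)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if not node.children:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = walk(child)
                below.append({k: v + bl for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            merged = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dists


def _canonical(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _iter_nodes(node: TreeNode):
    yield node
    for child, _ in node.children:
        yield from _iter_nodes(child)


def _newick(node: TreeNode) -> str:
    if not node.children:
        return node.name
    inner = ",".join(
        f"{_newick(child)}:{bl:.6f}" for child, bl in node.children
    )
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}"


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: at each step the joined pair minimises Q with ties
    broken by the smallest (i, j) index pair in the current node order.
    Negative branch-length estimates are clamped to zero and counted in
    ``clamped_branches``.
    """
    if np.isnan(matrix.values).any():
        raise ValueError(
            "distance matrix has undefined entries; exclude those taxa first"
        )
    n = len(matrix.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=t) for t in matrix.taxa]
    D = matrix.values.astype(float).copy()
    clamped = 0
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        bl_i = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        bl_j = D[i, j] - bl_i
        if bl_i < 0:
            bl_i = 0.0
            clamped += 1
        if bl_j < 0:
            bl_j = 0.0
            clamped += 1
        new_node = TreeNode(children=[(nodes[i], bl_i), (nodes[j], bl_j)])
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[new_idx, k] = D[k, new_idx] = d
        nodes.append(new_node)
        active = [k for k in active if k not in (i, j)] + [new_idx]
    i, j = active
    bl = D[i, j]
    if bl < 0:
        bl = 0.0
        clamped += 1
    root = TreeNode(children=[(nodes[i], bl / 2), (nodes[j], bl / 2)])
    return Tree(root, list(matrix.taxa), clamped)


def bootstrap_support(
    alignment: CodonAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    distance: str = "ds",
) -> tuple[Tree, dict]:
    """NJ tree on the full alignment with codon-bootstrap branch support.

    Codon columns are resampled with replacement per replicate; support
    for each internal bipartition of the full-data tree is the
    percentage of completed replicates containing it.  Replicates whose
    distance matrix has undefined entries are skipped and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_tree(ks_matrix(alignment, distance=distance))
    target = full.bipartitions()
    rng = np.random.default_rng(seed)
    hits = {bp: 0 for bp in target}
    completed = skipped = 0
    for _ in range(n_reps):
        rep = alignment.resample_codons(rng)
        mat = ks_matrix(rep, distance=distance)
        if np.isnan(mat.values).any():
            skipped += 1
            continue
        rep_bps = nj_tree(mat).bipartitions()
        completed += 1
        for bp in target & rep_bps:
            hits[bp] += 1
    all_taxa = frozenset(full.taxa)
    for node in _iter_nodes(full.root):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_taxa) - 1:
                bp = _canonical(side, all_taxa)
                child.support = (
                    100.0 * hits[bp] / completed if completed else 0.0
                )
    log = {"completed": completed, "skipped": skipped}
    return full, log
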