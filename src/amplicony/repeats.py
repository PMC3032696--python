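"""Ampliconic repeat structure: dot-plots, DR/IR arms, BAC-style assembly.

A dot-plot records every exact word match (default word size 10) between
two sequences, on both strands.  In a self-comparison, runs of
off-diagonal forward matches mark direct repeats (DRs) and runs of
reverse-complement matches on one anti-diagonal mark inverted repeats
(IRs); chaining those runs recovers the repeat arms, whose identity is
then measured by global alignment with gap columns excluded ("without
considering gaps").  Overlap-based contig chaining mirrors stringent
BAC assembly: suffix-prefix overlaps are accepted only above a length
and identity threshold (defaults >=30 kb at >=99.99%; relaxed tier
>=20 kb at >=99.85%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from Bio import Align

from .io import SequenceRecord, revcomp


@dataclass(frozen=True)
class WordMatch:
    i: int
    j: int
    strand: str  # "forward" or "revcomp"


@dataclass
class RepeatPair:
    arm_a: tuple  # (start, end) 0-based half-open on the contig
    arm_b: tuple
    orientation: str  # "DR" or "IR"
    identity: float | None = None
    n_words: int = 0

    @property
    def arm_length(self) -> int:
        return max(self.arm_a[1] - self.arm_a[0],
                   self.arm_b[1] - self.arm_b[0])


@dataclass
class OverlapEdge:
    seq_a: str
    seq_b: str
    overlap_length: int
    identity: float
    orientation: str  # orientation of seq_b relative to seq_a


def dotplot_matches(
    seq1: str, seq2: str, w: int = 10
) -> set[WordMatch]:
    """All exact length-w matches between seq1 and seq2, both strands.

    Forward matches pair seq1[i:i+w] with seq2[j:j+w]; reverse-complement
    matches pair seq1[i:i+w] with the reverse complement of seq2[j:j+w].
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) < w or len(seq2) < w:
        raise ValueError(f"both sequences must be at least {w} bp")
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq1) - w + 1):
        index[seq1[i : i + w]].append(i)
    matches: set[WordMatch] = set()
    rc2 = revcomp(seq2)
    n2 = len(seq2)
    for j in range(n2 - w + 1):
        word = seq2[j : j + w]
        for i in index.get(word, ()):
            matches.add(WordMatch(i, j, "forward"))
        rc_word = rc2[n2 - w - j : n2 - j]  # revcomp of seq2[j:j+w]
        for i in index.get(rc_word, ()):
            matches.add(WordMatch(i, j, "revcomp"))
    return matches


def detect_arm_pairs(
    matches: set[WordMatch],
    w: int = 10,
    min_arm: int = 1000,
    max_gap: int = 500,
) -> list[RepeatPair]:
    """Chain collinear self-comparison word matches into DR/IR candidates.

    Forward matches off the main diagonal share a diagonal (j - i) per
    DR; reverse-complement matches share an anti-diagonal (i + j) per
    IR.  Runs broken by gaps larger than ``max_gap`` split; candidates
    with arms shorter than ``min_arm`` are discarded.  Arms are reported
    with the lower-coordinate arm first.
    """
    diag_fwd: dict[int, list[int]] = defaultdict(list)
    diag_rc: dict[int, list[int]] = defaultdict(list)
    for m in matches:
        if m.strand == "forward":
            if m.j != m.i and m.j > m.i:  # dedupe symmetric pairs
                diag_fwd[m.j - m.i].append(m.i)
        else:
            if m.j > m.i:
                diag_rc[m.i + m.j].append(m.i)
    out: list[RepeatPair] = []
    for diag, starts in diag_fwd.items():
        for run_start, run_end, count in _chain(starts, w, max_gap):
            if run_end - run_start >= min_arm:
                out.append(
                    RepeatPair(
                        (run_start, run_end),
                        (run_start + diag, run_end + diag),
                        "DR", n_words=count,
                    )
                )
    for anti, starts in diag_rc.items():
        for run_start, run_end, count in _chain(starts, w, max_gap):
            if run_end - run_start >= min_arm:
                # partner arm occupies [anti - (run_end - w), anti + w - run_start)
                arm_b = (anti - run_end + w, anti + w - run_start)
                out.append(
                    RepeatPair((run_start, run_end), arm_b, "IR",
                               n_words=count)
                )
    out.sort(key=lambda r: (r.arm_a, r.arm_b))
    return _merge_overlapping(out)


def _chain(starts: list[int], w: int, max_gap: int):
    starts = sorted(set(starts))
    run_start = prev = starts[0]
    count = 1
    for s in starts[1:]:
        if s - prev > max_gap + w:
            yield run_start, prev + w, count
            run_start, count = s, 0
        prev = s
        count += 1
    yield run_start, prev + w, count


def _merge_overlapping(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Merge candidates of the same orientation whose both arms overlap."""
    merged: list[RepeatPair] = []
    for p in pairs:
        for q in merged:
            if (
                q.orientation == p.orientation
                and _overlaps(q.arm_a, p.arm_a)
                and _overlaps(q.arm_b, p.arm_b)
            ):
                q.arm_a = (min(q.arm_a[0], p.arm_a[0]),
                           max(q.arm_a[1], p.arm_a[1]))
                q.arm_b = (min(q.arm_b[0], p.arm_b[0]),
                           max(q.arm_b[1], p.arm_b[1]))
                q.n_words += p.n_words
                break
        else:
            merged.append(p)
    return merged


def _overlaps(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def arm_identity(
    arm_a_seq: str, arm_b_seq: str, orientation: str = "DR"
) -> float:
    """Percent identity between repeat arms, excluding gap columns.

    IR arm B is reverse-complemented before comparison.  Identity is
    matches over aligned non-gap columns x 100, from a global alignment
    (match +1, mismatch -1, gap open -5, extend -1).
    """
    if not arm_a_seq or not arm_b_seq:
        raise ValueError("arms must be non-empty")
    b = revcomp(arm_b_seq.upper()) if orientation == "IR" else arm_b_seq.upper()
    a = arm_a_seq.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    ta, tb = aln.aligned
    matches = columns = 0
    for (sa, ea), (sb, _) in zip(ta, tb):
        block_a = a[sa:ea]
        block_b = b[sb : sb + (ea - sa)]
        columns += ea - sa
        matches += sum(x == y for x, y in zip(block_a, block_b))
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def annotate_identities(
    contig: str, pairs: list[RepeatPair]
) -> list[RepeatPair]:
    for p in pairs:
        p.identity = arm_identity(
            contig[p.arm_a[0] : p.arm_a[1]],
            contig[p.arm_b[0] : p.arm_b[1]],
            p.orientation,
        )
    return pairs


# Reporting tiers for arm identity (percent): high-identity repeats,
# extended DRs, extended IRs.
IDENTITY_TIERS = {"high": 99.5, "dr_extended": 99.0, "ir_extended": 98.5}


def classify_tier(pair: RepeatPair) -> str | None:
    if pair.identity is None:
        return None
    if pair.identity >= IDENTITY_TIERS["high"]:
        return "high"
    if pair.orientation == "DR" and pair.identity >= IDENTITY_TIERS["dr_extended"]:
        return "dr_extended"
    if pair.orientation == "IR" and pair.identity >= IDENTITY_TIERS["ir_extended"]:
        return "ir_extended"
    return None


def plot_dotplot(
    matches: set[WordMatch], path, title: str = "dot-plot"
) -> None:
    """Basic dot-plot rendering: forward matches dark, RC matches light."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for strand, color in (("forward", "#333333"), ("revcomp", "#cc3333")):
        xs = [m.i for m in matches if m.strand == strand]
        ys = [m.j for m in matches if m.strand == strand]
        ax.plot(xs, ys, ".", markersize=0.5, color=color, label=strand)
    ax.set_xlabel("position in sequence 1 (bp)")
    ax.set_ylabel("position in sequence 2 (bp)")
    ax.set_title(title)
    ax.legend(markerscale=20, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Overlap assembly
# ---------------------------------------------------------------------------

_SEED_LEN = 64
_SEED_STRIDE = 64
_SEED_WINDOW = 4096


def _find_overlap(
    a: str, b: str, min_overlap: int, min_identity: float
) -> tuple[int, float] | None:
    """Best suffix(a)/prefix(b) overlap passing the thresholds.

    Seeds with exact 64-mers from b's prefix window (at >=99.85%
    identity an exact shared 64-mer exists with overwhelming
    probability), verifies the implied ungapped overlap, and returns
    (length, identity) of the longest accepted overlap.
    """
    import numpy as np

    best: tuple[int, float] | None = None
    seen_lengths: set[int] = set()
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    for s in range(0, min(len(b) - _SEED_LEN + 1, _SEED_WINDOW), _SEED_STRIDE):
        seed = b[s : s + _SEED_LEN]
        pos = a.find(seed)
        while pos != -1:
            ov = len(a) - pos + s
            if (
                min_overlap <= ov <= min(len(a), len(b))
                and ov not in seen_lengths
            ):
                seen_lengths.add(ov)
                mism = int(np.sum(arr_a[len(a) - ov :] != arr_b[:ov]))
                identity = 1.0 - mism / ov
                if identity >= min_identity and (
                    best is None or ov > best[0]
                ):
                    best = (ov, identity)
            pos = a.find(seed, pos + 1)
    return best


def find_overlap_edges(
    sequences: list[SequenceRecord], min_overlap: int, min_identity: float
) -> list[OverlapEdge]:
    """All accepted suffix-prefix overlap edges, both orientations."""
    edges = []
    oriented = {}
    for rec in sequences:
        oriented[(rec.id, "+")] = rec.sequence
        oriented[(rec.id, "-")] = revcomp(rec.sequence)
    for rec_a in sequences:
        for rec_b in sequences:
            if rec_a.id == rec_b.id:
                continue
            for orient in ("+", "-"):
                hit = _find_overlap(
                    rec_a.sequence, oriented[(rec_b.id, orient)],
                    min_overlap, min_identity,
                )
                if hit:
                    edges.append(
                        OverlapEdge(rec_a.id, rec_b.id, hit[0],
                                    100.0 * hit[1], orient)
                    )
    return edges


@dataclass
class ContigLayout:
    members: list  # (seq_id, offset, orientation)
    sequence: str


def assemble_overlaps(
    sequences: list[SequenceRecord],
    min_overlap: int = 30000,
    min_identity: float = 0.9999,
) -> tuple[list[ContigLayout], list[OverlapEdge]]:
    """Chain overlap edges into contig layouts.

    Only forward-orientation edges of unambiguous in/out degree are
    chained (a branching node ends its chain); sequences without
    accepted overlaps become singleton contigs.  The merged sequence
    takes the left sequence's bases across each overlap.
    """
    if not sequences:
        raise ValueError("no sequences to assemble")
    edges = find_overlap_edges(sequences, min_overlap, min_identity)
    fwd = [e for e in edges if e.orientation == "+"]
    out_edges: dict[str, list[OverlapEdge]] = defaultdict(list)
    in_deg: dict[str, int] = defaultdict(int)
    for e in fwd:
        out_edges[e.seq_a].append(e)
        in_deg[e.seq_b] += 1
    seq_by_id = {r.id: r.sequence for r in sequences}
    used: set[str] = set()
    contigs: list[ContigLayout] = []
    # chain starts: no incoming forward edge, or ambiguous incoming
    order = [r.id for r in sequences]
    for sid in order:
        if sid in used or in_deg.get(sid, 0) == 1:
            continue
        contigs.append(_walk_chain(sid, out_edges, seq_by_id, used))
    for sid in order:  # anything left sits on a cycle; break arbitrarily
        if sid not in used:
            contigs.append(_walk_chain(sid, out_edges, seq_by_id, used))
    return contigs, edges


def _walk_chain(start, out_edges, seq_by_id, used) -> ContigLayout:
    members = [(start, 0, "+")]
    used.add(start)
    seq = seq_by_id[start]
    current = start
    offset = 0
    while True:
        nxt = [e for e in out_edges.get(current, ()) if e.seq_b not in used]
        if len(nxt) != 1:
            break  # chain end or branching ambiguity
        e = nxt[0]
        offset += len(seq_by_id[current]) - e.overlap_length
        seq = seq[: offset] + seq_by_id[e.seq_b]
        members.append((e.seq_b, offset, "+"))
        used.add(e.seq_b)
        current = e.seq_b
    return ContigLayout(members, seq)
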