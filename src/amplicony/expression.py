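"""Locus-specific expression of near-identical gene copies.

Short paired reads cannot distinguish identical loci, so byte-identical
transcripts are first collapsed into unique references that carry their
copy number.  Each 36 bp mate is then aligned to both strands of every
reference allowing at most two substitutions; a pair counts only when
both mates hit a single reference, inward on opposite strands, with an
implied insert inside the library window.  Counted pairs are tiered:

  A  both mates within the mismatch budget,
  B  at least one mate a perfect match,
  C  both mates perfect,

and each tier is normalised as

  raw / copy_number x average_length / length x 1 / unique_sites

where ``unique_sites`` is the number of read-pair placements on the
reference whose implied 36-mers include at least one k-mer private to
that reference within the family.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import ReadPair, SequenceRecord, revcomp


@dataclass
class UniqueReference:
    ref_id: str
    member_locus_ids: list
    sequence: str
    unique_sites: int = -1  # -1 until computed

    @property
    def copy_number(self) -> int:
        return len(self.member_locus_ids)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    ref_id: str
    position: int
    strand: str
    mismatches: int


@dataclass
class PairVerdict:
    """Outcome of aligning one read pair against the reference set."""

    pair_id: str
    status: str                   # unique / multi / unmapped / discordant
    ref_id: str | None = None
    mm1: int | None = None
    mm2: int | None = None


@dataclass
class CategoryCounts:
    ref_id: str
    countA: int = 0
    countB: int = 0
    countC: int = 0


@dataclass
class NormalizedExpression:
    ref_id: str
    category: str
    raw: int
    normalized: float | None  # None when unique_sites == 0


# ---------------------------------------------------------------------------
# Reference collapsing
# ---------------------------------------------------------------------------

def collapse_identical(
    transcripts: list[SequenceRecord],
) -> list[UniqueReference]:
    """Group byte-identical transcripts into unique references.

    The reference id is the lexicographically smallest member id;
    references are returned sorted by ref_id.
    """
    if not transcripts:
        raise ValueError("no transcripts to collapse")
    groups: dict[str, list[str]] = defaultdict(list)
    for t in transcripts:
        groups[t.sequence.upper()].append(t.id)
    refs = [
        UniqueReference(min(ids), sorted(ids), seq)
        for seq, ids in groups.items()
    ]
    refs.sort(key=lambda r: r.ref_id)
    return refs


# ---------------------------------------------------------------------------
# Read alignment
# ---------------------------------------------------------------------------

class ReadAligner:
    """Substitution-only short-read aligner over a small reference set.

    Seeds with non-overlapping k-mers (pigeonhole: with <=2 mismatches
    over three 12-mers one seed chunk is exact) and verifies candidates
    by Hamming distance, which makes it exactly equivalent to an
    exhaustive scan of every position on both strands.
    """

    def __init__(self, refs: list[UniqueReference], config: RunConfig):
        self.refs = refs
        self.config = config
        L = config.read_length
        self.n_chunks = config.max_mismatches + 1
        self.chunk = L // self.n_chunks
        if self.chunk == 0:
            raise ValueError("read_length too short for seeding")
        self.index: dict[str, list] = defaultdict(list)
        self.strands: dict[tuple[str, str], str] = {}
        for ref in refs:
            for strand, seq in (("+", ref.sequence),
                                ("-", revcomp(ref.sequence))):
                self.strands[(ref.ref_id, strand)] = seq
                for start in range(0, len(seq) - self.chunk + 1):
                    self.index[seq[start : start + self.chunk]].append(
                        (ref.ref_id, strand, start)
                    )

    def hits_for_mate(self, mate: str) -> list[AlignmentHit]:
        """All positions on any reference/strand within the mismatch budget."""
        cfg = self.config
        L = cfg.read_length
        if len(mate) != L:
            raise ValueError(
                f"read length {len(mate)} != configured {L}"
            )
        candidates: set[tuple[str, str, int]] = set()
        for c in range(self.n_chunks):
            seed = mate[c * self.chunk : (c + 1) * self.chunk]
            for ref_id, strand, start in self.index.get(seed, ()):
                pos = start - c * self.chunk
                if pos >= 0:
                    candidates.add((ref_id, strand, pos))
        hits = []
        for ref_id, strand, pos in candidates:
            seq = self.strands[(ref_id, strand)]
            if pos + L > len(seq):
                continue
            mm = _hamming(mate, seq[pos : pos + L], cfg.max_mismatches)
            if mm is not None:
                # report positions on the forward reference coordinate
                fwd_pos = pos if strand == "+" else len(seq) - pos - L
                hits.append(AlignmentHit(ref_id, fwd_pos, strand, mm))
        hits.sort(key=lambda h: (h.ref_id, h.mismatches,
                                 0 if h.strand == "+" else 1, h.position))
        return hits

    def align_pair(self, pair: ReadPair) -> PairVerdict:
        return align_read_pair(pair, self, self.config)


def _hamming(a: str, b: str, budget: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def align_read_pair(
    pair: ReadPair, aligner: ReadAligner, config: RunConfig
) -> PairVerdict:
    """Classify one pair as unique / multi / unmapped / discordant.

    A mate is reference-unique iff all of its hits fall on exactly one
    reference.  The pair is ``unique`` iff both mates are
    reference-unique on the same reference, their best placements are on
    opposite strands in inward orientation, and the implied insert lies
    within the configured window.  Best placement per mate: fewest
    mismatches, then '+' strand, then smallest position.
    """
    hits1 = aligner.hits_for_mate(pair.mate1_seq)
    hits2 = aligner.hits_for_mate(pair.mate2_seq)
    if not hits1 or not hits2:
        return PairVerdict(pair.id, "unmapped")
    refs1 = {h.ref_id for h in hits1}
    refs2 = {h.ref_id for h in hits2}
    if len(refs1) > 1 or len(refs2) > 1:
        return PairVerdict(pair.id, "multi")
    if refs1 != refs2:
        return PairVerdict(pair.id, "discordant")
    ref_id = next(iter(refs1))
    best1 = _best_hit(hits1)
    best2 = _best_hit(hits2)
    if best1.strand == best2.strand:
        return PairVerdict(pair.id, "discordant", ref_id)
    plus, minus = (best1, best2) if best1.strand == "+" else (best2, best1)
    insert = minus.position + config.read_length - plus.position
    if not (plus.position <= minus.position
            and config.insert_min <= insert <= config.insert_max):
        return PairVerdict(pair.id, "discordant", ref_id)
    return PairVerdict(pair.id, "unique", ref_id,
                       best1.mismatches, best2.mismatches)


def _best_hit(hits: list[AlignmentHit]) -> AlignmentHit:
    return min(hits, key=lambda h: (h.mismatches,
                                    0 if h.strand == "+" else 1, h.position))


# ---------------------------------------------------------------------------
# Category counts and normalisation
# ---------------------------------------------------------------------------

def count_categories(
    verdicts: list[PairVerdict], refs: list[UniqueReference]
) -> list[CategoryCounts]:
    """Tier unique pairs into the A/B/C mismatch categories per reference."""
    by_ref = {r.ref_id: CategoryCounts(r.ref_id) for r in refs}
    for v in verdicts:
        if v.status != "unique":
            continue
        c = by_ref[v.ref_id]
        c.countA += 1
        if min(v.mm1, v.mm2) == 0:
            c.countB += 1
        if max(v.mm1, v.mm2) == 0:
            c.countC += 1
    return [by_ref[r.ref_id] for r in refs]


def count_unique_sites(
    ref: UniqueReference, refs: list[UniqueReference], config: RunConfig
) -> int:
    """Read-pair placements on ``ref`` identifiable as belonging to it.

    A placement (start, insert length) is unique iff at least one of its
    two implied read k-mers occurs, on either strand, in no other
    reference.  Exhaustive over all starts and insert lengths in
    [insert_min, insert_max].
    """
    L = config.read_length
    seq = ref.sequence
    if len(seq) < config.insert_min:
        return 0
    others: set[str] = set()
    for other in refs:
        if other.ref_id == ref.ref_id:
            continue
        s = other.sequence
        rc = revcomp(s)
        for start in range(len(s) - L + 1):
            others.add(s[start : start + L])
            others.add(rc[start : start + L])
    private = np.array(
        [seq[start : start + L] not in others
         for start in range(len(seq) - L + 1)],
        dtype=bool,
    )
    count = 0
    for insert in range(config.insert_min, config.insert_max + 1):
        n_starts = len(seq) - insert + 1
        if n_starts <= 0:
            continue
        left = private[:n_starts]
        right = private[insert - L : insert - L + n_starts]
        count += int(np.sum(left | right))
    return count


def compute_unique_sites(
    refs: list[UniqueReference], config: RunConfig
) -> None:
    """Annotate unique_sites on every reference with one shared k-mer index.

    Exactly equivalent to calling :func:`count_unique_sites` per
    reference, but builds a single map from k-mer to the number of
    distinct references containing it instead of rescanning the family
    for each reference.
    """
    L = config.read_length
    # k-mer -> (number of distinct refs containing it on the forward
    # strand, one such ref id)
    containing: dict[str, tuple[int, str]] = {}
    for ref in refs:
        seen: set[str] = set()
        s = ref.sequence
        for start in range(len(s) - L + 1):
            kmer = s[start : start + L]
            if kmer not in seen:
                seen.add(kmer)
                n, first = containing.get(kmer, (0, ref.ref_id))
                containing[kmer] = (n + 1, first)

    def in_other(kmer: str, ref_id: str) -> bool:
        for probe in (kmer, revcomp(kmer)):
            entry = containing.get(probe)
            if entry and (entry[0] > 1 or entry[1] != ref_id):
                return True
        return False

    for ref in refs:
        seq = ref.sequence
        if len(seq) < config.insert_min:
            ref.unique_sites = 0
            continue
        private = np.array(
            [not in_other(seq[start : start + L], ref.ref_id)
             for start in range(len(seq) - L + 1)],
            dtype=bool,
        )
        count = 0
        for insert in range(config.insert_min, config.insert_max + 1):
            n_starts = len(seq) - insert + 1
            if n_starts <= 0:
                continue
            left = private[:n_starts]
            right = private[insert - L : insert - L + n_starts]
            count += int(np.sum(left | right))
        ref.unique_sites = count


def normalize_counts(
    counts: CategoryCounts, ref: UniqueReference, avg_length: float
) -> list[NormalizedExpression]:
    """Apply raw/copy_number x avg_length/length x 1/unique_sites per tier."""
    if avg_length <= 0:
        raise ValueError("avg_length must be positive")
    if ref.unique_sites < 0:
        raise ValueError("unique_sites not computed for reference")
    out = []
    for cat, raw in (("A", counts.countA), ("B", counts.countB),
                     ("C", counts.countC)):
        if raw < 0:
            raise ValueError("negative raw count")
        if ref.unique_sites == 0:
            value = None
        else:
            value = (raw / ref.copy_number) * (avg_length / ref.length) \
                / ref.unique_sites
        out.append(NormalizedExpression(ref.ref_id, cat, raw, value))
    return out


def _ref_truth_level(members: str, truth_levels: dict) -> float | None:
    """Mean truth level over a collapsed reference's member loci."""
    vals = [truth_levels[m] for m in members.split(",") if m in truth_levels]
    return float(np.mean(vals)) if vals else None


@dataclass
class ExpressionSummary:
    family: str
    category: str
    n_refs: int
    max_fold_change: float | None
    mean_normalized: float | None


def quantify(
    transcripts: list[SequenceRecord],
    pairs: list[ReadPair],
    config: RunConfig | None = None,
    family_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """End-to-end quantification: collapse, align, count, normalise.

    Returns one row per unique reference with copy number, length,
    unique sites, raw A/B/C counts and their normalised values (NaN
    where unique_sites == 0).  ``family_map`` assigns loci to gene
    families; average length is taken within family.
    """
    config = config or RunConfig()
    refs = collapse_identical(transcripts)
    aligner = ReadAligner(refs, config)
    verdicts = [align_read_pair(p, aligner, config) for p in pairs]
    counts = count_categories(verdicts, refs)
    compute_unique_sites(refs, config)
    fam = family_map or {}
    families = {r.ref_id: fam.get(r.ref_id, "all") for r in refs}
    avg_len = {
        family: float(np.mean([r.length for r in refs
                               if families[r.ref_id] == family]))
        for family in set(families.values())
    }
    rows = []
    for ref, cc in zip(refs, counts):
        norm = normalize_counts(cc, ref, avg_len[families[ref.ref_id]])
        row = {
            "ref_id": ref.ref_id,
            "members": ",".join(ref.member_locus_ids),
            "family": families[ref.ref_id],
            "copy_number": ref.copy_number,
            "length": ref.length,
            "unique_sites": ref.unique_sites,
            "countA": cc.countA, "countB": cc.countB, "countC": cc.countC,
        }
        for n in norm:
            row[f"normalized{n.category}"] = (
                np.nan if n.normalized is None else n.normalized
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_expression(
    table: pd.DataFrame,
    truth_levels: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per family/category fold changes, means, and family-mean ratios.

    When per-locus truth levels are supplied, adds the Spearman
    correlation between normalised values and truth within family.
    """
    value_cols = ["normalizedA", "normalizedB", "normalizedC"]
    if not any(table[c].notna().any() for c in value_cols):
        raise ValueError("no defined normalised values to summarise")
    rows = []
    for family, sub in table.groupby("family"):
        for cat in "ABC":
            vals = sub[f"normalized{cat}"].dropna()
            pos = vals[vals > 0]
            fold = float(pos.max() / pos.min()) if len(pos) else None
            rho = None
            if truth_levels is not None:
                joined = sub.dropna(subset=[f"normalized{cat}"])
                tv = [_ref_truth_level(r, truth_levels)
                      for r in joined["members"]]
                keep = [k for k, v in enumerate(tv) if v is not None]
                vals = joined[f"normalized{cat}"].iloc[keep]
                tvals = [tv[k] for k in keep]
                if len(keep) >= 3 and len(set(tvals)) > 1 \
                        and vals.nunique() > 1:
                    rho = float(stats.spearmanr(vals, tvals).statistic)
            rows.append({
                "family": family, "category": cat, "n_refs": len(sub),
                "max_fold_change": fold,
                "mean_normalized": float(vals.mean()) if len(vals) else None,
                "spearman_vs_truth": rho,
            })
    out = pd.DataFrame(rows)
    fams = sorted(table["family"].unique())
    if len(fams) == 2:
        means = {
            (f, c): out[(out.family == f) & (out.category == c)]
            ["mean_normalized"].iloc[0]
            for f in fams for c in "ABC"
        }
        for c in "ABC":
            a, b = means[(fams[0], c)], means[(fams[1], c)]
            ratio = (a / b) if (a and b) else None
            out.loc[
                (out.category == c), "family_mean_ratio"
            ] = ratio
    return out
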