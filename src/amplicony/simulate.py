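"""Synthetic data with the statistical structure the analysis assumes.

The generative model is birth-and-death amplification of an ancestral
two-gene block: blocks duplicate as units under a Yule (pure-birth)
process, every lineage independently accrues neutral Jukes-Cantor
substitutions and occasional indels, and copies whose CDS picks up a
frameshifting indel or a premature stop codon become pseudogenes while
remaining transcribed.  Per-locus transcription levels span up to
60-fold within the main (B-like) family, with the second (A-like)
family averaging one-sixth of the first.  Reads are 2 x 36 bp pairs
drawn inward from 200-300 bp fragments with a small per-base
substitution error rate.

Every generator is deterministic given its parameters and seed, and
each emits the ground truth that downstream stages are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .genes import GeneModel, translate_to_first_stop
from .io import FeatureRecord, ReadPair, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(length: int, seed) -> str:
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def random_cds(n_aa: int, seed) -> str:
    """ATG + (n_aa - 1) random non-stop, non-ATG-free codons + TAA."""
    rng = _rng(seed)
    codons = ["ATG"]
    while len(codons) < n_aa:
        codon = random_dna(3, rng)
        if codon not in STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def mutate_jc(sequence: str, distance: float, seed) -> str:
    """Substitute each site under JC69 with branch length ``distance``.

    The per-site substitution probability is p* = (3/4)(1 - exp(-4d/3));
    a substituted site moves to one of the three other bases uniformly.
    N sites are left untouched.
    """
    if distance < 0:
        raise ValueError(f"branch length must be >= 0, got {distance}")
    if distance == 0 or not sequence:
        return sequence
    rng = _rng(seed)
    p = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    hit = (rng.random(arr.size) < p) & (idx >= 0)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx[hit] + shift) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

@dataclass
class AncestralGene:
    """One gene of the ancestral block: locus sequence plus its model."""

    record: SequenceRecord
    model: GeneModel
    cds_start: int   # locus coordinate of ATG
    cds_end: int     # locus coordinate just past the stop codon


@dataclass
class FamilyParams:
    """Rates and inputs of the birth-and-death family simulation.

    Units: duplication_rate is block duplications per extant block per
    My; substitution_rate is substitutions per site per My (neutral
    clock); indel_rate is indel events per locus per My.  total_time is
    the age of the family in My.
    """

    duplication_rate: float = 0.25
    substitution_rate: float = 0.0039
    indel_rate: float = 0.05
    indel_sizes: dict = field(
        default_factory=lambda: {
            13: 0.15, -8: 0.15, 1: 0.20, -1: 0.20, 3: 0.15, -3: 0.15,
        }
    )
    total_time: float = 19.6
    ancestral_block: tuple | None = None  # (AncestralGene B, AncestralGene A)
    seed: int = 0
    max_copies: int = 600

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "substitution_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if abs(sum(self.indel_sizes.values()) - 1.0) > 1e-9:
            raise ValueError("indel size probabilities must sum to 1")
        if any(s == 0 for s in self.indel_sizes):
            raise ValueError("indel sizes must be nonzero")


@dataclass
class LocusTruth:
    """Ground truth for one simulated gene-family copy."""

    locus_id: str
    parent_id: str | None
    birth_time: float           # Mya before present
    family: str                 # "B-like" or "A-like"
    indel_events: list          # (position, signed size, kind, in_cds)
    is_active: bool
    expression_level: float = 0.0
    model: GeneModel | None = None
    cds_start: int = 0
    cds_end: int = 0


@dataclass
class _GeneState:
    seq: str
    intron_start: int
    intron_end: int
    cds_start: int
    cds_end: int
    ancestor_aa: int
    events: list = field(default_factory=list)


def make_ancestral_block(
    seed: int = 0,
    b_aa: int = 543,
    a_aa: int = 400,
    exon1_len: int = 100,
    intron_len: int = 300,
    utr3_len: int = 250,
    utr5_gap: int = 71,
) -> tuple[AncestralGene, AncestralGene]:
    """Build the ancestral two-gene block.

    Each gene has two exons with the whole CDS in exon 2 and the single
    intron in the 5'-UTR ending ``utr5_gap`` bp upstream of the start
    codon.  Default CDS lengths follow the 543-aa main-family peptide
    and a shorter second family.  Intron and UTR lengths are desk-scale
    stand-ins for the multi-kb real features.
    """
    rng = _rng(seed)
    genes = []
    for n_aa in (b_aa, a_aa):
        cds = random_cds(n_aa, rng)
        exon1 = random_dna(exon1_len, rng)
        intron = "GT" + random_dna(intron_len - 4, rng) + "AG"
        utr5 = random_dna(utr5_gap, rng)
        utr3 = random_dna(utr3_len, rng)
        seq = exon1 + intron + utr5 + cds + utr3
        cds_start = exon1_len + intron_len + utr5_gap
        model = GeneModel(
            intron_start=exon1_len,
            intron_end=exon1_len + intron_len,
            cds_offset_in_exon2=utr5_gap,
            utr5_intron_gap=utr5_gap,
        )
        genes.append(
            AncestralGene(
                SequenceRecord("ancestral", seq), model, cds_start,
                cds_start + len(cds),
            )
        )
    return genes[0], genes[1]


def _evolve_gene(state: _GeneState, dt: float, params: FamilyParams,
                 rng: np.random.Generator) -> None:
    if dt <= 0:
        return
    old = state.seq
    state.seq = mutate_jc(state.seq, params.substitution_rate * dt, rng)
    if not _cds_frameshift(state.events):
        # purifying selection on still-functional copies: substitutions
        # that would introduce an in-frame premature stop are rejected,
        # so indels are the pseudogenization channel; frameshifted
        # copies are dead already and evolve fully neutrally
        seq = list(state.seq)
        for k in range(state.cds_start, state.cds_end - 3, 3):
            if "".join(seq[k : k + 3]) in STOPS:
                seq[k : k + 3] = old[k : k + 3]
        state.seq = "".join(seq)
    n_indels = rng.poisson(params.indel_rate * dt)
    sizes = list(params.indel_sizes)
    probs = np.array([params.indel_sizes[s] for s in sizes], dtype=float)
    for _ in range(n_indels):
        size = int(sizes[rng.choice(len(sizes), p=probs)])
        if size > 0:
            pos = int(rng.integers(0, len(state.seq) + 1))
            _apply_insertion(state, pos, size, rng)
        else:
            pos = int(rng.integers(0, len(state.seq)))
            _apply_deletion(state, pos, -size)


def _apply_insertion(state: _GeneState, pos: int, size: int,
                     rng: np.random.Generator) -> None:
    insert = random_dna(size, rng)
    state.seq = state.seq[:pos] + insert + state.seq[pos:]
    in_cds = state.cds_start < pos < state.cds_end
    for attr in ("intron_start", "intron_end", "cds_start", "cds_end"):
        val = getattr(state, attr)
        if val >= pos and not (attr == "cds_end" and in_cds):
            setattr(state, attr, val + size)
    if in_cds:
        state.cds_end += size
    state.events.append((pos, size, "ins", in_cds))


def _apply_deletion(state: _GeneState, pos: int, size: int) -> None:
    size = min(size, len(state.seq) - pos)
    if size <= 0:
        return
    lo, hi = pos, pos + size
    ov = max(0, min(hi, state.cds_end) - max(lo, state.cds_start))
    state.seq = state.seq[:lo] + state.seq[hi:]
    for attr in ("intron_start", "intron_end", "cds_start", "cds_end"):
        val = getattr(state, attr)
        setattr(state, attr, val - min(max(0, val - lo), size))
    state.events.append((pos, -size, "del", ov > 0, ov))


def _cds_frameshift(events) -> bool:
    for ev in events:
        if ev[2] == "ins" and ev[3] and ev[1] % 3 != 0:
            return True
        if ev[2] == "del" and ev[3] and ev[4] % 3 != 0:
            return True
    return False


def _net_inframe_cds_indel(events) -> int:
    net = 0
    for ev in events:
        if ev[2] == "ins" and ev[3]:
            net += ev[1]
        elif ev[2] == "del" and ev[3]:
            net -= ev[4]
    return net


def simulate_family(
    params: FamilyParams,
) -> tuple[list[LocusTruth], list[SequenceRecord]]:
    """Simulate the amplified two-gene family.

    Blocks duplicate as units under a pure-birth process over
    ``total_time``; both genes of a block share its duplication history
    but evolve independently.  Returns the per-locus truth (birth times,
    indels, activity) and the evolved locus sequences.  Truth entries
    also carry each locus's updated gene model for downstream splicing.
    """
    rng = _rng(params.seed)
    expected = 2 * np.exp(params.duplication_rate * params.total_time)
    if expected > params.max_copies:
        raise ValueError(
            f"expected copy number {expected:.0f} exceeds cap "
            f"{params.max_copies}; reduce duplication_rate or total_time"
        )
    if params.ancestral_block is None:
        block = make_ancestral_block(seed=rng.integers(2**31))
    else:
        block = params.ancestral_block

    # --- genealogy: pure-birth on blocks, forward in time -----------------
    births = {0: params.total_time}
    parents: dict[int, int | None] = {0: None}
    events: list[tuple[float, int, int]] = []  # (time Mya, parent, child)
    extant = [0]
    next_id = 1
    t = params.total_time
    while params.duplication_rate > 0:
        rate = len(extant) * params.duplication_rate
        t -= rng.exponential(1.0 / rate)
        if t <= 0:
            break
        src = extant[rng.integers(len(extant))]
        births[next_id] = t
        parents[next_id] = src
        events.append((t, src, next_id))
        extant.append(next_id)
        next_id += 1
        if len(extant) > params.max_copies:
            raise ValueError(
                f"copy number exceeded cap {params.max_copies} during "
                "simulation; reduce duplication_rate or total_time"
            )

    # --- sequence evolution along the block genealogy ---------------------
    def initial_state(gene: AncestralGene) -> _GeneState:
        m = gene.model
        return _GeneState(
            seq=gene.record.sequence,
            intron_start=m.intron_start,
            intron_end=m.intron_end,
            cds_start=gene.cds_start,
            cds_end=gene.cds_end,
            ancestor_aa=(gene.cds_end - gene.cds_start) // 3 - 1,
        )

    states = {0: (initial_state(block[0]), initial_state(block[1]))}
    clock = {0: params.total_time}
    for t_ev, src, child in events:
        for g in states[src]:
            _evolve_gene(g, clock[src] - t_ev, params, rng)
        clock[src] = t_ev
        states[child] = (
            _copy_state(states[src][0]), _copy_state(states[src][1])
        )
        clock[child] = t_ev
    for bid in states:
        for g in states[bid]:
            _evolve_gene(g, clock[bid], params, rng)
        clock[bid] = 0.0

    # --- truth assembly ----------------------------------------------------
    truth: list[LocusTruth] = []
    records: list[SequenceRecord] = []
    for bid in sorted(states):
        for fam, tag, g in (
            ("B-like", "B", states[bid][0]), ("A-like", "A", states[bid][1])
        ):
            locus_id = f"{tag}{bid:03d}"
            parent_id = (
                None if parents[bid] is None else f"{tag}{parents[bid]:03d}"
            )
            frameshift = _cds_frameshift(g.events)
            region = g.seq[g.cds_start :]
            peptide, stop = translate_to_first_stop(region)
            expected_aa = g.ancestor_aa + _net_inframe_cds_indel(g.events) // 3
            premature = stop is not None and peptide < expected_aa
            model = GeneModel(
                intron_start=g.intron_start,
                intron_end=g.intron_end,
                cds_offset_in_exon2=g.cds_start - g.intron_end,
            )
            truth.append(
                LocusTruth(
                    locus_id=locus_id,
                    parent_id=parent_id,
                    birth_time=births[bid],
                    family=fam,
                    indel_events=list(g.events),
                    is_active=not frameshift and not premature,
                    model=model,
                    cds_start=g.cds_start,
                    cds_end=g.cds_end,
                )
            )
            records.append(SequenceRecord(locus_id, g.seq))
    return truth, records


def _copy_state(state: _GeneState) -> _GeneState:
    return _GeneState(
        seq=state.seq,
        intron_start=state.intron_start,
        intron_end=state.intron_end,
        cds_start=state.cds_start,
        cds_end=state.cds_end,
        ancestor_aa=state.ancestor_aa,
        events=list(state.events),
    )


def transcripts_from_family(
    truth: list[LocusTruth], records: list[SequenceRecord]
) -> list[SequenceRecord]:
    """Spliced transcript of every locus (intron removed)."""
    seq_by_id = {r.id: r.sequence for r in records}
    out = []
    for t in truth:
        seq = seq_by_id[t.locus_id]
        m = t.model
        out.append(
            SequenceRecord(t.locus_id, seq[: m.intron_start] + seq[m.intron_end :])
        )
    return out


def simulate_star_family(
    n_loci_b: int = 20,
    n_loci_a: int = 20,
    divergence: float = 0.12,
    n_duplicate_pairs: int = 2,
    transcript_len: int = 2000,
    seed: int = 0,
) -> tuple[list[LocusTruth], list[SequenceRecord]]:
    """Family of transcripts with star-like divergence from one ancestor.

    Each locus transcript is the ancestral transcript of its family
    evolved independently by ``divergence`` substitutions per site
    (pairwise divergence about twice that), which gives every locus
    private sequence -- the regime in which short-read locus-specific
    quantification is informative.  ``n_duplicate_pairs`` loci per
    family receive a byte-identical twin to exercise copy-number
    collapsing.  A genealogical family (recent duplicates nearly
    identical) is produced by :func:`simulate_family` instead.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = _rng(seed)
    truth: list[LocusTruth] = []
    records: list[SequenceRecord] = []
    for fam, tag, n_loci in (("B-like", "B", n_loci_b),
                             ("A-like", "A", n_loci_a)):
        ancestor = random_dna(transcript_len, rng)
        k = 0
        for i in range(n_loci):
            seq = mutate_jc(ancestor, divergence, rng)
            twins = 2 if i < n_duplicate_pairs else 1
            for _ in range(twins):
                locus_id = f"{tag}{k:03d}"
                truth.append(
                    LocusTruth(locus_id, None, 0.0, fam, [], True)
                )
                records.append(SequenceRecord(locus_id, seq))
                k += 1
    return truth, records


# ---------------------------------------------------------------------------
# Expression levels
# ---------------------------------------------------------------------------

def assign_expression(
    truth: list[LocusTruth],
    max_fold: float = 60.0,
    family_a_scale: float = 1.0 / 6.0,
    a_max_fold: float = 10.0,
    seed: int = 0,
) -> list[LocusTruth]:
    """Draw per-locus transcription levels and store them in the truth.

    B-like loci get levels log-uniform on [1, max_fold]; A-like loci get
    log-uniform levels on [1, a_max_fold] rescaled so the realised
    A-family mean equals ``family_a_scale`` times the B-family mean.
    Pseudogenes are transcribed like active copies.
    """
    if max_fold < 1:
        raise ValueError("max_fold must be >= 1")
    if family_a_scale <= 0:
        raise ValueError("family_a_scale must be positive")
    rng = _rng(seed)
    b_loci = [t for t in truth if t.family == "B-like"]
    a_loci = [t for t in truth if t.family == "A-like"]
    for t in b_loci:
        t.expression_level = float(
            np.exp(rng.uniform(0.0, np.log(max_fold))) if max_fold > 1 else 1.0
        )
    raw_a = np.exp(rng.uniform(0.0, np.log(a_max_fold), size=len(a_loci)))
    if len(a_loci) and len(b_loci):
        target_mean = family_a_scale * float(
            np.mean([t.expression_level for t in b_loci])
        )
        raw_a = raw_a * target_mean / raw_a.mean()
    for t, level in zip(a_loci, raw_a):
        t.expression_level = float(level)
    return truth


# ---------------------------------------------------------------------------
# Read pairs
# ---------------------------------------------------------------------------

def simulate_read_pairs(
    transcripts: list[SequenceRecord],
    truth: list[LocusTruth],
    n_pairs: int,
    error_rate: float = 0.001,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sample inward-facing 2 x read_length pairs from the transcripts.

    Fragments come from loci with probability proportional to
    expression_level x transcript length; insert lengths are uniform on
    [insert_min, insert_max]; mate 1 is the fragment's first
    ``read_length`` bases and mate 2 the reverse complement of its last
    ``read_length`` bases.  Per-base substitution errors occur at
    ``error_rate``.  Returns the pairs and a truth table mapping each
    pair to its source locus.
    """
    config = config or RunConfig()
    rng = _rng(config.seed if seed is None else seed)
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    level = {t.locus_id: t.expression_level for t in truth}
    for tr in transcripts:
        if len(tr) <= config.insert_max:
            raise ValueError(
                f"transcript {tr.id!r} (length {len(tr)}) is not longer "
                f"than insert_max={config.insert_max}"
            )
    weights = np.array(
        [level.get(tr.id, 0.0) * len(tr) for tr in transcripts], dtype=float
    )
    if n_pairs and weights.sum() <= 0:
        raise ValueError("all transcript sampling weights are zero")
    pairs: list[ReadPair] = []
    sources = []
    if n_pairs:
        probs = weights / weights.sum()
        choice = rng.choice(len(transcripts), size=n_pairs, p=probs)
        L = config.read_length
        for k in range(n_pairs):
            tr = transcripts[choice[k]]
            insert = int(rng.integers(config.insert_min, config.insert_max + 1))
            start = int(rng.integers(0, len(tr) - insert + 1))
            frag = tr.sequence[start : start + insert]
            mate1 = _seq_errors(frag[:L], error_rate, rng)
            mate2 = _seq_errors(revcomp(frag[-L:]), error_rate, rng)
            pair_id = f"pair{k:07d}"
            pairs.append(ReadPair(pair_id, mate1, mate2))
            sources.append((pair_id, tr.id, start, insert))
    table = pd.DataFrame(
        sources, columns=["pair_id", "locus_id", "start", "insert"]
    )
    return pairs, table


def _seq_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    hit = (rng.random(arr.size) < error_rate) & (idx >= 0)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx[hit] + shift) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Ampliconic contig layout
# ---------------------------------------------------------------------------

@dataclass
class AmpliconPlan:
    """Order/orientation of repeat units along a synthetic contig."""

    unit_order: list  # (block_id, orientation in {"forward", "revcomp"})
    spacer_lengths: list  # n_units + 1 junction spacer sizes

    def __post_init__(self) -> None:
        if len(self.spacer_lengths) != len(self.unit_order) + 1:
            raise ValueError("need one spacer per junction (n_units + 1)")
        if any(s < 0 for s in self.spacer_lengths):
            raise ValueError("spacer lengths must be >= 0")
        for _, orient in self.unit_order:
            if orient not in {"forward", "revcomp"}:
                raise ValueError(f"unknown orientation {orient!r}")


def layout_amplicon(
    blocks: list[SequenceRecord], plan: AmpliconPlan, seed: int = 0,
    contig_id: str = "amplicon",
) -> tuple[SequenceRecord, list[FeatureRecord]]:
    """Concatenate oriented repeat units with random spacers.

    Same-orientation repeats of a unit form direct repeats by
    construction; opposite orientations form inverted repeats.  Features
    record each unit's interval and strand on the contig.
    """
    rng = _rng(seed)
    by_id = {b.id: b for b in blocks}
    parts = [random_dna(plan.spacer_lengths[0], rng)]
    features = []
    offset = plan.spacer_lengths[0]
    for (block_id, orient), spacer in zip(
        plan.unit_order, plan.spacer_lengths[1:]
    ):
        if block_id not in by_id:
            raise KeyError(f"unknown block id {block_id!r}")
        seq = by_id[block_id].sequence
        if orient == "revcomp":
            seq = revcomp(seq)
        parts.append(seq)
        features.append(
            FeatureRecord(
                contig_id, offset, offset + len(seq),
                "+" if orient == "forward" else "-",
                "repeat_unit", {"ID": block_id},
            )
        )
        offset += len(seq)
        parts.append(random_dna(spacer, rng))
        offset += spacer
    return SequenceRecord(contig_id, "".join(parts)), features


def tile_sequence(
    sequence: str, n_tiles: int, overlap: int, id_prefix: str = "tile"
) -> list[SequenceRecord]:
    """Cut a sequence into n_tiles overlapping pieces with exact overlaps.

    Consecutive tiles share exactly ``overlap`` bp; together they cover
    the input, so error-free assembly must reproduce it byte-for-byte.
    """
    L = len(sequence)
    if n_tiles < 1:
        raise ValueError("need at least one tile")
    step = (L - overlap) / n_tiles
    tile_len = int(np.ceil(step)) + overlap
    tiles = []
    for k in range(n_tiles):
        start = round(k * step)
        end = min(L, start + tile_len) if k < n_tiles - 1 else L
        tiles.append(SequenceRecord(f"{id_prefix}{k:02d}", sequence[start:end]))
    return tiles


# ---------------------------------------------------------------------------
# Dating helpers
# ---------------------------------------------------------------------------

def simulate_outgroup_cds(
    ancestral_gene: AncestralGene, params: FamilyParams, seed: int
) -> str:
    """Evolve the ancestral CDS along an independent sister lineage.

    The sister species diverged at ``total_time``, so its ortholog
    carries ``substitution_rate x total_time`` expected substitutions
    per site on its own branch (the family's loci carry the same on
    theirs, giving 2rt between species).
    """
    cds = ancestral_gene.record.sequence[
        ancestral_gene.cds_start : ancestral_gene.cds_end
    ]
    return mutate_jc(cds, params.substitution_rate * params.total_time, seed)


def deepest_split_time(truth: list[LocusTruth], locus_ids: list[str]) -> float:
    """Oldest divergence time (Mya) among the named loci.

    Two lineages split when the younger of their block ancestries
    branches off the shared ancestral block; the deepest split is the
    maximum over pairs.  Loci of both families map to the same block
    genealogy.
    """
    by_id = {t.locus_id: t for t in truth}

    def ancestry(locus_id: str) -> list[tuple[str, float]]:
        chain = []
        node = by_id[locus_id]
        while True:
            chain.append((node.locus_id[1:], node.birth_time))  # block key
            if node.parent_id is None:
                return chain
            node = by_id[node.parent_id]

    chains = {lid: ancestry(lid) for lid in locus_ids}
    deepest = 0.0
    ids = list(locus_ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ca = chains[ids[i]]
            cb = chains[ids[j]]
            blocks_b = {blk: k for k, (blk, _) in enumerate(cb)}
            split = None
            for k, (blk, _) in enumerate(ca):
                if blk in blocks_b:
                    # departure times of each lineage from the shared block
                    t_a = ca[k - 1][1] if k > 0 else None
                    kb = blocks_b[blk]
                    t_b = cb[kb - 1][1] if kb > 0 else None
                    candidates = [t for t in (t_a, t_b) if t is not None]
                    split = max(candidates) if candidates else 0.0
                    break
            if split is not None:
                deepest = max(deepest, split)
    return deepest


# ---------------------------------------------------------------------------
# Engineered frameshift fixture
# ---------------------------------------------------------------------------

def engineer_frameshift_fixture(
    ref_aa: int = 543,
    del_pos: int = 1218,
    del_size: int = 8,
    stop_at: int = 1273,
) -> tuple[str, str]:
    """Reference CDS plus a copy with a frame-shifting deletion.

    Builds a ``ref_aa``-residue reference CDS from stop-free alanine
    codons, deletes ``del_size`` bp at 1-based CDS position ``del_pos``,
    and places bases so that the first stop codon in the shifted frame
    begins exactly at CDS position ``stop_at`` of the mutated sequence.
    Both the reference (stop-free until its terminator) and the mutated
    copy (first stop at ``stop_at``) are verified by direct translation.
    """
    ref = list("ATG" + "GCT" * (ref_aa - 1) + "TAA")
    # mutated index m (0-based) maps to reference index m + del_size
    # for m >= del_pos - 1; impose TAA at mutated stop_at..stop_at+2
    for offset, base in enumerate("TAA"):
        ref[stop_at - 1 + offset + del_size] = base
    reference = "".join(ref)
    n_aa, stop = translate_to_first_stop(reference)
    if stop != 3 * ref_aa + 1 or n_aa != ref_aa:
        raise RuntimeError("reference engineering failed: premature stop")
    mutated = reference[: del_pos - 1] + reference[del_pos - 1 + del_size :]
    pep, stop = translate_to_first_stop(mutated)
    if stop != stop_at or pep != (stop_at - 1) // 3:
        raise RuntimeError(
            f"fixture engineering failed: first stop at {stop}, wanted {stop_at}"
        )
    return reference, mutated
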