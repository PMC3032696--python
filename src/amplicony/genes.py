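"""Splice-aware coding assessment of gene-family copies.

Each locus in the family carries a two-exon gene whose entire CDS sits in
exon 2, with the single intron in the 5'-UTR ending a fixed distance
(default 71 bp) upstream of the start codon.  A copy is called a
pseudogene when a frameshifting indel or a premature stop codon truncates
the predicted peptide below configurable thresholds; otherwise it is
called active.  Amplified copies fall into structural types: full-length
("A-like"), frameshifted by an insertion ("B-like"), frameshifted by a
deletion ("C-like"), or "other".

The premature-stop convention used throughout: ``premature_stop_start``
is the 1-based position, in CDS numbering of the assessed transcript, of
the stop codon's first base, so the encoded peptide has
``(premature_stop_start - 1) / 3`` residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    """Exon/intron layout of one locus, in locus (contig) coordinates."""

    intron_start: int
    intron_end: int
    cds_offset_in_exon2: int = 71
    exon_count: int = 2
    utr5_intron_gap: int = 71

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")
        if self.intron_start > self.intron_end:
            raise ValueError("intron interval reversed")

    def cds_start_in_transcript(self) -> int:
        """Transcript offset of the start codon once the intron is spliced out."""
        return self.intron_start + self.cds_offset_in_exon2


@dataclass
class ORF:
    """An ATG-to-stop open reading frame on a transcript (forward strand).

    ``start``/``end`` are 0-based half-open transcript coordinates of the
    coding region, excluding the stop codon; ``peptide_aa`` is its length
    in residues.
    """

    start: int
    end: int
    frame: int
    peptide_aa: int


@dataclass
class ClassifierThresholds:
    """Peptide-length thresholds separating active copies from pseudogenes."""

    min_aa: int = 200
    min_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must lie in (0, 1]")


@dataclass
class CodingAssessment:
    locus_id: str = ""
    indels: list = field(default_factory=list)  # (ref position 1-based, signed bp)
    frameshift: bool = False
    premature_stop_start: int | None = None  # 1-based CDS coord of stop's 1st base
    peptide_aa: int = 0
    structural_type: str = "other"
    status: str = ""


def splice_transcript(
    locus_sequence: str, model: GeneModel
) -> tuple[str, bool]:
    """Concatenate exons; flag whether the intron has consensus GT-AG ends."""
    seq = locus_sequence.upper()
    if not (0 <= model.intron_start <= model.intron_end <= len(seq)):
        raise IndexError(
            f"intron [{model.intron_start}, {model.intron_end}) outside "
            f"locus of length {len(seq)}"
        )
    intron = seq[model.intron_start : model.intron_end]
    transcript = seq[: model.intron_start] + seq[model.intron_end :]
    valid = intron.startswith("GT") and intron.endswith("AG")
    return transcript, valid


def find_orfs(transcript: str, min_aa: int = 0) -> list[ORF]:
    """All forward-frame ATG-to-stop ORFs with peptide >= min_aa.

    Every ATG paired with its first downstream in-frame stop yields one
    ORF (nested ATGs give nested ORFs).  Sorted by peptide length,
    longest first; ties by start coordinate.
    """
    seq = transcript.upper()
    orfs: list[ORF] = []
    for frame in range(3):
        pending: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                pending.append(pos)
            elif codon in STOP_CODONS:
                for start in pending:
                    aa = (pos - start) // 3
                    if aa >= min_aa:
                        orfs.append(ORF(start, pos, frame, aa))
                pending = []
    orfs.sort(key=lambda o: (-o.peptide_aa, o.start))
    return orfs


def peptide_length_from_stop(stop_start: int) -> int:
    """Peptide residues encoded before a stop codon beginning at CDS
    position ``stop_start`` (1-based)."""
    if stop_start < 1 or (stop_start - 1) % 3 != 0:
        raise ValueError(
            f"stop codon start {stop_start} is not in frame "
            "(must be 1-based and congruent to 1 mod 3)"
        )
    return (stop_start - 1) // 3


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # Trailing transcript sequence past the reference stop (3'-UTR) is free.
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def _validate_reference(reference_cds: str) -> int:
    if len(reference_cds) % 3 != 0 or len(reference_cds) < 6:
        raise ValueError("reference CDS length must be a positive multiple of 3")
    if not reference_cds.startswith("ATG"):
        raise ValueError("reference CDS must begin with ATG")
    if reference_cds[-3:] not in STOP_CODONS:
        raise ValueError("reference CDS must end with a stop codon")
    return len(reference_cds) // 3 - 1  # peptide length


def translate_to_first_stop(cds: str) -> tuple[int, int | None]:
    """Translate from position 0; return (peptide_aa, stop_start or None).

    ``stop_start`` is the 1-based CDS position of the first in-frame stop
    codon's first base; None when translation runs off the end.
    """
    for pos in range(0, len(cds) - 2, 3):
        if cds[pos : pos + 3] in STOP_CODONS:
            return pos // 3, pos + 1
    return len(cds) // 3, None


def assess_coding(
    transcript: str,
    reference_cds: str,
    model: GeneModel | None = None,
    locus_id: str = "",
) -> CodingAssessment:
    """Compare a transcript's CDS region to the reference CDS.

    The CDS region starts at the model-determined start codon (or at
    position 0 when no model is given) and runs to the transcript end;
    trailing sequence beyond the reference stop is not penalised.  Indels
    are read off a global alignment (match +1, mismatch -1, gap open -5,
    extend -1, first reported alignment for determinism) and located by
    1-based reference coordinate.  The peptide is obtained by direct
    translation of the (possibly frameshifted) CDS region to its first
    stop codon.
    """
    transcript = transcript.upper()
    reference_cds = reference_cds.upper()
    ref_aa = _validate_reference(reference_cds)
    cds_start = model.cds_start_in_transcript() if model is not None else 0
    region = transcript[cds_start:]
    if not region:
        raise ValueError(f"locus {locus_id!r}: empty CDS region")

    aligner = _make_aligner()
    aln = aligner.align(region, reference_cds)[0]
    target_blocks, query_blocks = aln.aligned

    indels: list[tuple[int, int]] = []
    for k in range(1, len(target_blocks)):
        t_gap = target_blocks[k][0] - target_blocks[k - 1][1]
        q_gap = query_blocks[k][0] - query_blocks[k - 1][1]
        ref_pos = query_blocks[k - 1][1]  # 0-based ref coord where gap opens
        if t_gap and not q_gap:
            indels.append((ref_pos + 1, t_gap))  # insertion in transcript
        elif q_gap and not t_gap:
            indels.append((ref_pos + 1, -q_gap))  # deletion from reference
    # leading overhangs (alignment does not start at 0) count as end indels
    if query_blocks.size and query_blocks[0][0] > 0:
        indels.insert(0, (1, -int(query_blocks[0][0])))
    if query_blocks.size and query_blocks[-1][1] < len(reference_cds):
        tail = len(reference_cds) - int(query_blocks[-1][1])
        indels.append((int(query_blocks[-1][1]) + 1, -tail))

    frameshift = any(size % 3 != 0 for _, size in indels)

    peptide_aa, stop_start = translate_to_first_stop(region)
    # in-frame indels legitimately change the expected peptide length
    expected_aa = ref_aa
    if not frameshift:
        expected_aa += sum(size for _, size in indels) // 3
    premature = stop_start is not None and peptide_aa < expected_aa
    assessment = CodingAssessment(
        locus_id=locus_id,
        indels=indels,
        frameshift=frameshift,
        premature_stop_start=stop_start if premature else None,
        peptide_aa=peptide_aa if stop_start is not None else 0,
        structural_type=_structural_type(indels, frameshift, peptide_aa,
                                         expected_aa, premature),
    )
    return assessment


def _structural_type(
    indels, frameshift: bool, peptide_aa: int, ref_aa: int, premature: bool
) -> str:
    if not indels and not premature and peptide_aa == ref_aa:
        return "A-like"
    if frameshift:
        shifting = [size for _, size in indels if size % 3 != 0]
        if all(size > 0 for size in shifting):
            return "B-like"
        if all(size < 0 for size in shifting):
            return "C-like"
    return "other"


def classify_locus(
    assessment: CodingAssessment,
    reference_aa: int,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Call a copy active or pseudogene from its predicted peptide length.

    Active iff peptide_aa >= max(min_aa, ceil(min_fraction * reference_aa)).
    """
    if reference_aa <= 0:
        raise ValueError("reference peptide length must be positive")
    thresholds = thresholds or ClassifierThresholds()
    cutoff = max(
        thresholds.min_aa, math.ceil(thresholds.min_fraction * reference_aa)
    )
    status = "active" if assessment.peptide_aa >= cutoff else "pseudogene"
    assessment.status = status
    return status


def translate(cds: str) -> str:
    """Straight translation helper (standard code, no stop trimming)."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
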