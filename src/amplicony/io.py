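"""Readers and writers for the flat formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package.  On
disk, GFF3 is 1-based inclusive and BED is 0-based half-open; the two
conversions here are mutually inverse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class PairingError(ValueError):
    """Raised when two FASTQ mate files cannot be paired record-by-record."""


@dataclass
class SequenceRecord:
    """One named DNA sequence (a BAC, locus, transcript or reference CDS)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"sequence for record {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A paired-end read: two mates sequenced inward from one fragment."""

    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_quals: str = ""
    mate2_quals: str = ""

    def __post_init__(self) -> None:
        if not self.mate1_quals:
            self.mate1_quals = "I" * len(self.mate1_seq)
        if not self.mate2_quals:
            self.mate2_quals = "I" * len(self.mate2_seq)
        if len(self.mate1_quals) != len(self.mate1_seq) or len(
            self.mate2_quals
        ) != len(self.mate2_seq):
            raise ValueError(f"quality/sequence length mismatch for {self.id!r}")


@dataclass
class FeatureRecord:
    """A located feature on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature on {self.contig_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, uppercased, in file order."""
    if format != "fasta":
        raise ValueError(f"unsupported sequence format: {format!r}")
    path = Path(path)
    _check_fasta_shape(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq), description=rec.description)
        )
    return records


def _check_fasta_shape(path: Path) -> None:
    """Line-level validation so errors can name the offending line."""
    have_header = False
    have_seq = False
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if have_header and not have_seq:
                    raise ParseError(
                        f"{path}: empty sequence for header at line {header_line}"
                    )
                if not line[1:].strip():
                    raise ParseError(f"{path}: malformed header at line {lineno}")
                have_header, have_seq, header_line = True, False, lineno
            else:
                if not have_header:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                have_seq = True
    if have_header and not have_seq:
        raise ParseError(f"{path}: empty sequence for header at line {header_line}")


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# FASTQ pairs
# ---------------------------------------------------------------------------

_MATE_SUFFIX = re.compile(r"/[12]$")


def parse_read_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two mate FASTQ files into ReadPairs, checking id agreement."""
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise PairingError(
            f"mate files have {len(recs1)} and {len(recs2)} records; "
            f"first unpaired record index {min(len(recs1), len(recs2))}"
        )
    pairs = []
    for idx, (r1, r2) in enumerate(zip(recs1, recs2)):
        id1 = _MATE_SUFFIX.sub("", r1.id)
        id2 = _MATE_SUFFIX.sub("", r2.id)
        if id1 != id2:
            raise PairingError(
                f"record {idx}: mate ids disagree ({r1.id!r} vs {r2.id!r})"
            )
        q1 = "".join(
            chr(q + 33) for q in r1.letter_annotations["phred_quality"]
        )
        q2 = "".join(
            chr(q + 33) for q in r2.letter_annotations["phred_quality"]
        )
        pairs.append(ReadPair(id1, str(r1.seq).upper(), str(r2.seq).upper(), q1, q2))
    return pairs


def write_read_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.mate1_seq}\n+\n{p.mate1_quals}\n")
            f2.write(f"@{p.id}/2\n{p.mate2_seq}\n+\n{p.mate2_quals}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def write_features(
    features: Iterable[FeatureRecord], path: str | Path, format: str = "gff3"
) -> None:
    """Write features as GFF3 (1-based inclusive) or BED (0-based half-open)."""
    if format not in {"gff3", "bed"}:
        raise ValueError(f"unknown feature format: {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attributes.items()))
                fh.write(
                    f"{f.contig_id}\tamplicony\t{f.feature_type}\t"
                    f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs or '.'}\n"
                )
        else:
            for f in features:
                name = f.attributes.get("ID", f.feature_type)
                fh.write(
                    f"{f.contig_id}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n"
                )


def parse_features(path: str | Path, format: str = "gff3") -> list[FeatureRecord]:
    """Read features back into internal 0-based half-open coordinates."""
    if format not in {"gff3", "bed"}:
        raise ValueError(f"unknown feature format: {format!r}")
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "gff3":
                if len(cols) < 9:
                    raise ParseError(f"{path}: short GFF3 line {lineno}")
                attrs = {}
                if cols[8] != ".":
                    for item in cols[8].split(";"):
                        if item:
                            k, _, v = item.partition("=")
                            attrs[k] = v
                feats.append(
                    FeatureRecord(
                        cols[0], int(cols[3]) - 1, int(cols[4]), cols[6], cols[2],
                        attrs,
                    )
                )
            else:
                if len(cols) < 6:
                    raise ParseError(f"{path}: short BED line {lineno}")
                feats.append(
                    FeatureRecord(
                        cols[0], int(cols[1]), int(cols[2]), cols[5], cols[3],
                        {"ID": cols[3]},
                    )
                )
    return feats
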