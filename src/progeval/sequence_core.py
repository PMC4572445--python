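"""Nucleotide sequence handling for proteogenomic annotation QC.

Provides the genomic substrate every other stage builds on: replicon
containers with GC metadata, six-frame translation with an exact
amino-acid-to-genome coordinate map, and maximal (stop-to-stop) ORF
enumeration.

Coordinate conventions
----------------------
All intervals are 0-based, half-open ``[start, end)`` on the forward
genomic axis; conversion to 1-based inclusive happens only at GFF3
boundaries.  Reading-frame labels are intrinsic to the strand-oriented
reading: on '+' the frame of a codon starting at ``s`` is ``s % 3``; on
'-' the frame of a codon ending at genomic ``e`` is ``(length - e) % 3``.
Under this convention a frame label equals the translation offset on the
strand-oriented sequence for both strands, so frame comparison between
peptides and gene calls is well defined.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")
#: Alternative prokaryotic initiation codons (genetic code table 11).
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
BACTERIAL_TABLE = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content in percent; N positions are excluded from both numerator
    and denominator."""
    n_valid = len(seq) - seq.count("N")
    if n_valid == 0:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / n_valid


@dataclass(frozen=True)
class Replicon:
    """A named nucleotide sequence (chromosome or plasmid).

    ``length`` and ``gc_percent`` are derived from ``seq`` and always
    consistent with it.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        for pos, base in enumerate(self.seq):
            if base not in NUCLEOTIDES:
                raise ValueError(
                    f"replicon {self.id!r}: invalid nucleotide {base!r} "
                    f"at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.seq)


def _translate_oriented(sub: str, table: int) -> str:
    """Translate a strand-oriented nucleotide string codon-by-codon.

    Any codon containing N translates to 'X' (even when the ambiguity
    would resolve, e.g. GGN): peptides must never match across unknown
    sequence.
    """
    aa = str(Seq(sub).translate(table=table))
    if "N" in sub:
        chars = list(aa)
        pos = sub.find("N")
        while pos != -1:
            chars[pos // 3] = "X"
            pos = sub.find("N", pos + 1)
        aa = "".join(chars)
    return aa


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual readings of a replicon.

    ``aa_seq`` uses '*' for stop codons and 'X' for codons containing N.
    ``frame_offset`` is the offset on the strand-oriented sequence and
    equals the intrinsic frame label of every codon in this reading.
    """

    replicon_id: str
    strand: str  # '+' or '-'
    frame_offset: int  # 0, 1, 2
    aa_seq: str
    replicon_length: int

    @property
    def frame(self) -> int:
        return self.frame_offset

    def codon_interval(self, aa_index: int) -> tuple[int, int]:
        """Genomic half-open interval of the codon producing ``aa_seq[aa_index]``."""
        return self.genomic_interval(aa_index, aa_index + 1)

    def genomic_interval(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Genomic interval covered by the aa slice ``[aa_start, aa_end)``."""
        if not (0 <= aa_start <= aa_end <= len(self.aa_seq)):
            raise IndexError("aa slice out of range")
        if self.strand == "+":
            return (self.frame_offset + 3 * aa_start, self.frame_offset + 3 * aa_end)
        L = self.replicon_length
        return (L - self.frame_offset - 3 * aa_end, L - self.frame_offset - 3 * aa_start)

    def aa_slice(self, gstart: int, gend: int) -> tuple[int, int]:
        """Inverse of :meth:`genomic_interval`; raises if not codon-aligned."""
        if self.strand == "+":
            a, rem = divmod(gstart - self.frame_offset, 3)
            b = (gend - self.frame_offset) // 3
        else:
            L = self.replicon_length
            a, rem = divmod(L - self.frame_offset - gend, 3)
            b = (L - self.frame_offset - gstart) // 3
        if rem or (gend - gstart) % 3:
            raise ValueError("interval is not codon-aligned with this frame")
        return a, b


def translate_frames(replicon: Replicon, table: int = BACTERIAL_TABLE) -> list[FrameTranslation]:
    """Six-frame translation of a replicon (3 offsets x 2 strands).

    Reverse-strand readings are translations of the reverse complement.
    """
    out: list[FrameTranslation] = []
    L = replicon.length
    for strand in "+-":
        oriented = replicon.seq if strand == "+" else revcomp(replicon.seq)
        for offset in range(3):
            n_codons = (L - offset) // 3
            sub = oriented[offset : offset + 3 * n_codons]
            out.append(
                FrameTranslation(
                    replicon_id=replicon.id,
                    strand=strand,
                    frame_offset=offset,
                    aa_seq=_translate_oriented(sub, table),
                    replicon_length=L,
                )
            )
    return out


@dataclass(frozen=True)
class Orf:
    """A maximal stop-to-stop open reading frame (no internal in-frame stop),
    bounded by in-frame stops or the sequence edge.  The interval excludes
    the bounding stop codons."""

    replicon_id: str
    strand: str
    start: int
    end: int
    frame: int
    has_start_codon: bool


def find_orfs(
    replicon: Replicon,
    min_len_nt: int = 39,
    table: int = BACTERIAL_TABLE,
) -> list[Orf]:
    """Enumerate maximal ORFs of length >= ``min_len_nt`` on both strands.

    The 39 nt default is the shortest experimentally confirmed CDS
    (the PatS peptide); ab initio callers typically use 81-120 nt.
    ``has_start_codon`` records whether any in-frame ATG/GTG/TTG occurs
    inside the ORF.
    """
    if min_len_nt < 3:
        raise ValueError(f"min_len_nt must be >= 3, got {min_len_nt}")
    orfs: list[Orf] = []
    for strand in "+-":
        oriented = replicon.seq if strand == "+" else revcomp(replicon.seq)
        for ft in translate_frames(replicon, table=table):
            if ft.strand != strand:
                continue
            aa = ft.aa_seq
            off = ft.frame_offset
            seg_start = 0
            for i, ch in enumerate(aa + "*"):  # sentinel stop at the edge
                if ch != "*":
                    continue
                if (i - seg_start) * 3 >= min_len_nt:
                    gstart, gend = ft.genomic_interval(seg_start, i)
                    has_start = any(
                        oriented[off + 3 * j : off + 3 * j + 3] in START_CODONS
                        for j in range(seg_start, i)
                    )
                    orfs.append(
                        Orf(replicon.id, strand, gstart, gend, ft.frame, has_start)
                    )
                seg_start = i + 1
    orfs.sort(key=lambda o: (o.replicon_id, o.start, o.end, o.strand))
    return orfs


class FrameIndex:
    """Shared six-frame translations plus in-frame stop positions for a set
    of replicons.  Built once and reused by the peptide mapper and the
    conflict classifier for maximal-ORF queries."""

    def __init__(self, replicons: Iterable[Replicon], table: int = BACTERIAL_TABLE):
        self.replicons: dict[str, Replicon] = {}
        self.frames: dict[tuple[str, str, int], FrameTranslation] = {}
        self._stops: dict[tuple[str, str, int], list[int]] = {}
        for rep in replicons:
            if rep.id in self.replicons:
                raise ValueError(f"duplicate replicon id {rep.id!r}")
            self.replicons[rep.id] = rep
            for ft in translate_frames(rep, table=table):
                key = (rep.id, ft.strand, ft.frame_offset)
                self.frames[key] = ft
                self._stops[key] = [i for i, c in enumerate(ft.aa_seq) if c == "*"]

    def frame(self, replicon_id: str, strand: str, frame: int) -> FrameTranslation:
        return self.frames[(replicon_id, strand, frame)]

    def iter_frames(self) -> Iterator[FrameTranslation]:
        return iter(self.frames.values())

    def orf_bounds(
        self, replicon_id: str, strand: str, frame: int, gstart: int, gend: int
    ) -> tuple[int, int] | None:
        """Genomic bounds of the maximal ORF containing codon-aligned
        ``[gstart, gend)``, or None if an in-frame stop lies inside it."""
        key = (replicon_id, strand, frame)
        ft = self.frames[key]
        a, b = ft.aa_slice(gstart, gend)
        stops = self._stops[key]
        i = bisect.bisect_left(stops, a)
        if i < len(stops) and stops[i] < b:
            return None
        lo = stops[i - 1] + 1 if i > 0 else 0
        hi = stops[i] if i < len(stops) else len(ft.aa_seq)
        return ft.genomic_interval(lo, hi)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a (multi-)FASTA file; record id up to first whitespace becomes
    the replicon id."""
    reps = [Replicon(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not reps:
        raise ValueError(f"no FASTA records in {path}")
    return reps


def write_fasta(replicons: Iterable[Replicon], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in replicons
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns
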