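"""Exact unique peptide-to-genome mapping against six-frame translations.

A peptide maps if its amino-acid sequence occurs exactly once across all
six translation frames of all replicons of the input genome; peptides
occurring more than once are ambiguous and discarded, peptides occurring
nowhere are unmatched.  I and L are treated as distinct residues, and
matching never crosses a stop ('*') or unknown ('X') position.  Peptides
arriving with trusted pre-mapped coordinates are validated by
re-translation instead of searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation_io import PeptideInput
from .sequence_core import (
    BACTERIAL_TABLE,
    FrameIndex,
    Replicon,
    _translate_oriented,
    revcomp,
)

logger = logging.getLogger(__name__)

#: Peptides shorter than this many residues are flagged as high ambiguity
#: risk in the report (they are still processed).
SHORT_PEPTIDE_AA = 6


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide with its unique genomic locus.

    ``end - start == 3 * len(aa_seq)`` and re-translating ``[start, end)``
    on ``strand`` reproduces ``aa_seq``.
    """

    peptide_id: str
    aa_seq: str
    replicon_id: str
    strand: str
    start: int
    end: int
    frame: int
    n_genomic_hits: int = 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def locus(self) -> tuple[str, str, int, int]:
        """Genomic-interval identity used for non-redundancy counting."""
        return (self.replicon_id, self.strand, self.start, self.end)


@dataclass
class MappingReport:
    """Partition of the peptide input: mapped + ambiguous + unmatched."""

    n_input: int = 0
    n_mapped: int = 0
    n_ambiguous_discarded: int = 0
    n_unmatched: int = 0
    n_short_flagged: int = 0
    statuses: list[tuple[str, str]] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_input == (
            self.n_mapped + self.n_ambiguous_discarded + self.n_unmatched
        ), "mapping report does not partition the input"


def _as_index(replicons, table: int) -> FrameIndex:
    if isinstance(replicons, FrameIndex):
        return replicons
    return FrameIndex(replicons, table=table)


def _occurrences(index: FrameIndex, aa: str, limit: int = 2) -> list[tuple]:
    """Locations of ``aa`` across all frames, stopping once ``limit``
    occurrences prove ambiguity."""
    hits: list[tuple] = []
    for key in sorted(index.frames):
        ft = index.frames[key]
        pos = ft.aa_seq.find(aa)
        while pos != -1:
            hits.append((ft, pos))
            if len(hits) >= limit:
                return hits
            pos = ft.aa_seq.find(aa, pos + 1)
    return hits


def _validate_coordinates(p: PeptideInput, index: FrameIndex,
                          table: int) -> MappedPeptide | None:
    rep = index.replicons.get(p.replicon_id)
    if rep is None or p.strand not in "+-" or p.end is None:
        return None
    if not (0 <= p.start < p.end <= rep.length):
        return None
    if p.end - p.start != 3 * len(p.aa_seq):
        return None
    nt = rep.seq[p.start : p.end]
    if p.strand == "-":
        nt = revcomp(nt)
    if _translate_oriented(nt, table) != p.aa_seq:
        return None
    frame = p.start % 3 if p.strand == "+" else (rep.length - p.end) % 3
    return MappedPeptide(
        p.peptide_id, p.aa_seq, p.replicon_id, p.strand, p.start, p.end, frame
    )


def map_peptide(
    p: PeptideInput,
    replicons: Iterable[Replicon] | FrameIndex,
    table: int = BACTERIAL_TABLE,
    trust_coordinates: bool = True,
) -> tuple[str, MappedPeptide | None]:
    """Map one peptide.  Returns ``(status, mapped-or-None)`` with status
    one of ``mapped``, ``ambiguous``, ``unmatched``."""
    index = _as_index(replicons, table)
    if trust_coordinates and p.has_coordinates:
        mp = _validate_coordinates(p, index, table)
        if mp is not None:
            return "mapped", mp
        logger.warning(
            "peptide %s: pre-mapped coordinates failed re-translation; "
            "treated as unmatched", p.peptide_id,
        )
        return "unmatched", None
    hits = _occurrences(index, p.aa_seq, limit=2)
    if len(hits) == 0:
        return "unmatched", None
    if len(hits) > 1:
        return "ambiguous", None
    ft, aa_pos = hits[0]
    start, end = ft.genomic_interval(aa_pos, aa_pos + len(p.aa_seq))
    return "mapped", MappedPeptide(
        p.peptide_id, p.aa_seq, ft.replicon_id, ft.strand, start, end, ft.frame
    )


def map_all(
    peptides: Sequence[PeptideInput],
    replicons: Iterable[Replicon] | FrameIndex,
    table: int = BACTERIAL_TABLE,
    trust_coordinates: bool = True,
) -> tuple[list[MappedPeptide], MappingReport]:
    """Map every peptide; the report counts partition the input exactly.

    The result is independent of peptide and replicon order (each peptide
    is mapped against the whole genome independently).
    """
    index = _as_index(replicons, table)
    report = MappingReport(n_input=len(peptides))
    mapped: list[MappedPeptide] = []
    for p in peptides:
        if len(p.aa_seq) < SHORT_PEPTIDE_AA:
            report.n_short_flagged += 1
        status, mp = map_peptide(p, index, table=table,
                                 trust_coordinates=trust_coordinates)
        report.statuses.append((p.peptide_id, status))
        if status == "mapped":
            report.n_mapped += 1
            mapped.append(mp)
        elif status == "ambiguous":
            report.n_ambiguous_discarded += 1
        else:
            report.n_unmatched += 1
    report.check()
    return mapped, report


def write_mapping_tsv(mapped: Sequence[MappedPeptide], report: MappingReport,
                      path) -> None:
    """Flat mapping table: one row per input peptide with its status and,
    when mapped, its locus."""
    by_id: dict[str, list[MappedPeptide]] = {}
    for mp in mapped:
        by_id.setdefault(mp.peptide_id, []).append(mp)
    used: dict[str, int] = {}
    lines = ["peptide_id\tstatus\treplicon\tstart\tend\tstrand\tframe"]
    for pid, status in report.statuses:
        if status == "mapped":
            i = used.get(pid, 0)
            used[pid] = i + 1
            mp = by_id[pid][i]
            lines.append(
                f"{pid}\t{status}\t{mp.replicon_id}\t{mp.start}\t{mp.end}"
                f"\t{mp.strand}\t{mp.frame}"
            )
        else:
            lines.append(f"{pid}\t{status}\t.\t.\t.\t.\t.")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
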