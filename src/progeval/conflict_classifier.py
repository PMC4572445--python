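"""Peptide support, conflict detection, and wrong/short/missed error
classification with pseudogene re-scoring.

The scoring rules automate the manual curation procedure for peptides
that disagree with a caller's gene model:

* a call overlapped by >= 2 non-redundant peptides that all share a
  reading frame different from the call's is **wrong**;
* a call with >= 2 non-redundant in-frame peptides starting 5' of its
  annotated start — each inside the call's maximal in-frame ORF
  extension (no in-frame stop may separate a peptide from the start it
  contradicts) — is **short**, with the implied start at the most 5'
  supporting peptide;
* >= 2 non-redundant peptides sharing strand and frame inside one
  maximal ORF that overlaps no call imply a **missed** gene, reported as
  the (stop-to-stop) ORF since the true start is unknowable from
  peptides alone;
* a pseudogene-tagged call whose retained CDS fragments contain >= 2
  confirming peptides is re-scored as a **missed** real gene; an
  untagged frameshifted (multi-fragment) call with confirming peptides
  is a good call and yields no error.

Non-redundancy means distinct genomic intervals: re-observations of the
same locus count once, overlapping distinct tryptic peptides count
separately.  Supporting a gene requires strand and frame agreement with
the fragment the peptide lies in, not mere spatial containment —
otherwise a wholly-contained wrong-frame peptide could never expose a
wrong call.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import GeneCall, GeneCallSet
from .peptide_mapper import MappedPeptide
from .sequence_core import FrameIndex, Replicon

RELATIONS = ("outside_all", "overlaps_out_of_frame", "extends_upstream",
             "spans_boundary")


@dataclass(frozen=True)
class ConflictRecord:
    """A mapped peptide that does not support any call of one caller,
    labelled with its geometric relation to that caller's gene set."""

    peptide: MappedPeptide
    caller_id: str
    relation: str
    nearest_call: GeneCall | None = None


@dataclass(frozen=True)
class ErrorCall:
    """A classified annotation error with its peptide evidence.

    ``subject_call`` is the contradicted call (absent for missed genes);
    ``implied_interval`` is the start extension for short calls and the
    implied (maximal-ORF or pseudogene-locus) gene for wrong/missed.
    """

    category: str  # wrong | short | missed
    caller_id: str
    replicon_id: str
    strand: str
    implied_interval: tuple[int, int]
    supporting_peptides: tuple[MappedPeptide, ...]
    n_nonredundant: int
    subject_call: GeneCall | None = None


@dataclass
class SupportSummary:
    """Per-caller peptide support and gene coverage."""

    caller_id: str
    n_supporting_peptides: int
    n_conflicting_peptides: int
    n_genes_with_peptide: int
    n_genes_total: int
    coverage_percent: float


def _replicon_lengths(replicons: Iterable[Replicon] | FrameIndex) -> dict[str, int]:
    if isinstance(replicons, FrameIndex):
        return {rid: r.length for rid, r in replicons.replicons.items()}
    return {r.id: r.length for r in replicons}


def _as_frame_index(replicons) -> FrameIndex:
    if isinstance(replicons, FrameIndex):
        return replicons
    return FrameIndex(replicons)


def supports(pep: MappedPeptide, call: GeneCall, replicon_length: int) -> bool:
    """True iff the peptide lies wholly inside the call's interval, on the
    call's strand, in the frame of a CDS fragment it overlaps."""
    if pep.strand != call.strand:
        return False
    if pep.start < call.start or pep.end > call.end:
        return False
    frames = call.fragment_frames(replicon_length)
    for (a, b), fr in zip(call.fragments, frames):
        if pep.start < b and pep.end > a and fr == pep.frame:
            return True
    return False


def peptide_support(
    mapped: Sequence[MappedPeptide],
    calls: GeneCallSet,
    replicons: Iterable[Replicon] | FrameIndex,
) -> SupportSummary:
    """Count supporting peptides and peptide coverage of genes.

    A gene is *covered* when at least one peptide maps wholly inside it
    (strand- and frame-consistently); ``coverage_percent`` is the
    percentage of the caller's genes so covered.
    """
    lengths = _replicon_lengths(replicons)
    n_support = 0
    covered: set[tuple] = set()
    for pep in mapped:
        hit = False
        for call in calls.overlapping(pep.replicon_id, pep.start, pep.end):
            if supports(pep, call, lengths[pep.replicon_id]):
                covered.add(call.key)
                hit = True
        if hit:
            n_support += 1
    n_total = len(calls)
    return SupportSummary(
        caller_id=calls.caller_id,
        n_supporting_peptides=n_support,
        n_conflicting_peptides=len(mapped) - n_support,
        n_genes_with_peptide=len(covered),
        n_genes_total=n_total,
        coverage_percent=100.0 * len(covered) / n_total if n_total else 0.0,
    )


def _call_orf_bounds(index: FrameIndex, call: GeneCall,
                     lengths: dict[str, int]) -> tuple[int, int] | None:
    """Maximal-ORF bounds of the call's 5'-terminal fragment (the stop
    codon inside the call interval is excluded from the query)."""
    L = lengths[call.replicon_id]
    if call.strand == "+":
        a, b = call.fragments[0]
        b = min(b, a + 3 * ((b - a) // 3))
        query = (a, a + 3)
    else:
        a, b = call.fragments[-1]
        a = max(a, b - 3 * ((b - a) // 3))
        query = (b - 3, b)
    frame = call.fragment_frames(L)[0 if call.strand == "+" else -1]
    try:
        return index.orf_bounds(call.replicon_id, call.strand, frame, *query)
    except (KeyError, ValueError):
        return None


def _extends_5prime(pep: MappedPeptide, call: GeneCall) -> bool:
    if call.strand == "+":
        return pep.start < call.start
    return pep.end > call.end


def _extends_3prime(pep: MappedPeptide, call: GeneCall) -> bool:
    if call.strand == "+":
        return pep.end > call.end
    return pep.start < call.start


def _in_upstream_extension(pep: MappedPeptide, call: GeneCall,
                           orf: tuple[int, int] | None) -> bool:
    """Peptide lies in the same maximal ORF as the call's start, 5' of it."""
    if orf is None:
        return False
    return orf[0] <= pep.start and pep.end <= orf[1] and _extends_5prime(pep, call)


def find_conflicts(
    mapped: Sequence[MappedPeptide],
    calls: GeneCallSet,
    replicons: Iterable[Replicon] | FrameIndex,
) -> list[ConflictRecord]:
    """Label every non-supporting mapped peptide with its relation to the
    caller's gene set.

    Peptides that overlap no call but lie in-frame within the maximal-ORF
    upstream extension of one are classed ``extends_upstream`` (they
    contradict that call's start); only peptides in call-free ORF
    territory are ``outside_all``.
    """
    index = _as_frame_index(replicons)
    lengths = _replicon_lengths(index)
    orf_cache: dict[tuple, tuple[int, int] | None] = {}
    conflicts: list[ConflictRecord] = []

    for pep in mapped:
        L = lengths[pep.replicon_id]
        overl = calls.overlapping(pep.replicon_id, pep.start, pep.end)
        if any(supports(pep, c, L) for c in overl):
            continue
        in_frame = [
            c for c in overl
            if c.strand == pep.strand and pep.frame in c.fragment_frames(L)
        ]
        if in_frame:
            def ovlen(c: GeneCall) -> int:
                return min(pep.end, c.end) - max(pep.start, c.start)
            call = max(in_frame, key=lambda c: (ovlen(c), -c.start))
            if _extends_5prime(pep, call):
                rel = "extends_upstream"
            elif _extends_3prime(pep, call):
                rel = "spans_boundary"
            else:
                # contained in the call but in no frame-consistent fragment
                rel = "overlaps_out_of_frame"
            conflicts.append(ConflictRecord(pep, calls.caller_id, rel, call))
            continue
        if overl:
            def ovlen(c: GeneCall) -> int:
                return min(pep.end, c.end) - max(pep.start, c.start)
            call = max(overl, key=lambda c: (ovlen(c), -c.start))
            conflicts.append(
                ConflictRecord(pep, calls.caller_id, "overlaps_out_of_frame", call)
            )
            continue
        # no overlap at all: check for an in-frame call whose upstream
        # ORF extension contains this peptide
        orf = index.orf_bounds(pep.replicon_id, pep.strand, pep.frame,
                               pep.start, pep.end)
        upstream_call = None
        if orf is not None:
            for c in calls.overlapping(pep.replicon_id, *orf):
                if c.strand != pep.strand:
                    continue
                ckey = (c.key, calls.caller_id)
                if ckey not in orf_cache:
                    orf_cache[ckey] = _call_orf_bounds(index, c, lengths)
                if orf_cache[ckey] == orf and _extends_5prime(pep, c):
                    upstream_call = c
                    break
        if upstream_call is not None:
            conflicts.append(
                ConflictRecord(pep, calls.caller_id, "extends_upstream",
                               upstream_call)
            )
        else:
            conflicts.append(
                ConflictRecord(pep, calls.caller_id, "outside_all", None)
            )
    return conflicts


def _nonredundant(peps: Iterable[MappedPeptide]) -> list[MappedPeptide]:
    seen: dict[tuple, MappedPeptide] = {}
    for p in peps:
        seen.setdefault(p.locus, p)
    return sorted(seen.values(), key=lambda p: p.locus)


def classify_errors(
    conflicts: Sequence[ConflictRecord],
    calls: GeneCallSet,
    replicons: Iterable[Replicon] | FrameIndex,
    min_support: int = 2,
) -> list[ErrorCall]:
    """Apply the wrong/short/missed scoring rules to a caller's conflicts.

    Every error requires at least ``min_support`` non-redundant peptides
    (distinct genomic intervals).  Relations feed disjoint categories, so
    no peptide contributes to two errors of different categories against
    the same caller.  ``spans_boundary`` conflicts feed no category.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    index = _as_frame_index(replicons)
    lengths = _replicon_lengths(index)
    errors: list[ErrorCall] = []

    # --- short: in-frame peptides upstream of an annotated start --------
    by_call: dict[tuple, list[MappedPeptide]] = defaultdict(list)
    call_of: dict[tuple, GeneCall] = {}
    for rec in conflicts:
        if rec.relation == "extends_upstream":
            by_call[rec.nearest_call.key].append(rec.peptide)
            call_of[rec.nearest_call.key] = rec.nearest_call
    for ckey in sorted(by_call):
        call = call_of[ckey]
        orf = _call_orf_bounds(index, call, lengths)
        peps = _nonredundant(
            p for p in by_call[ckey] if _in_upstream_extension(p, call, orf)
        )
        if len(peps) < min_support:
            continue
        if call.strand == "+":
            implied = (min(p.start for p in peps), call.end)
        else:
            implied = (call.start, max(p.end for p in peps))
        errors.append(
            ErrorCall("short", calls.caller_id, call.replicon_id, call.strand,
                      implied, tuple(peps), len(peps), subject_call=call)
        )

    # --- wrong: out-of-frame peptides over a call, sharing one frame ----
    by_call_frame: dict[tuple, list[MappedPeptide]] = defaultdict(list)
    for rec in conflicts:
        if rec.relation == "overlaps_out_of_frame" and rec.nearest_call is not None:
            key = (rec.nearest_call.key, rec.peptide.strand, rec.peptide.frame)
            by_call_frame[key].append(rec.peptide)
            call_of[rec.nearest_call.key] = rec.nearest_call
    for key in sorted(by_call_frame):
        ckey, strand, frame = key
        call = call_of[ckey]
        groups: dict[tuple | None, list[MappedPeptide]] = defaultdict(list)
        for p in _nonredundant(by_call_frame[key]):
            orf = index.orf_bounds(p.replicon_id, strand, frame, p.start, p.end)
            groups[orf].append(p)
        for orf in sorted(g for g in groups if g is not None):
            peps = groups[orf]
            if len(peps) < min_support:
                continue
            errors.append(
                ErrorCall("wrong", calls.caller_id, call.replicon_id, strand,
                          orf, tuple(peps), len(peps), subject_call=call)
            )

    # --- missed: peptides in call-free territory, grouped by ORF --------
    by_orf: dict[tuple, list[MappedPeptide]] = defaultdict(list)
    for rec in conflicts:
        if rec.relation != "outside_all":
            continue
        p = rec.peptide
        orf = index.orf_bounds(p.replicon_id, p.strand, p.frame, p.start, p.end)
        if orf is None:
            continue
        by_orf[(p.replicon_id, p.strand, p.frame, orf)].append(p)
    for key in sorted(by_orf):
        rid, strand, frame, orf = key
        peps = _nonredundant(by_orf[key])
        if len(peps) < min_support:
            continue
        errors.append(
            ErrorCall("missed", calls.caller_id, rid, strand, orf,
                      tuple(peps), len(peps), subject_call=None)
        )

    errors.sort(key=lambda e: (e.replicon_id, e.implied_interval, e.category))
    return errors


def rescore_pseudogenes(
    errors: Sequence[ErrorCall],
    calls: GeneCallSet,
    mapped: Sequence[MappedPeptide],
    replicons: Iterable[Replicon] | FrameIndex,
    min_support: int = 2,
) -> list[ErrorCall]:
    """Re-score pseudogene calls against confirming peptides.

    A pseudogene-tagged call whose fragments hold >= ``min_support``
    non-redundant confirming (in-frame, contained) peptides is evidence
    of a real, expressed gene: it yields a *missed* error at the call's
    locus.  Untagged frameshifted calls with confirming peptides remain
    good calls.  Confirming peptides are supporting peptides, so they
    never also appear in conflict-derived errors.
    """
    lengths = _replicon_lengths(replicons)
    out = list(errors)
    for call in calls:
        if not call.is_pseudogene:
            continue
        confirming = _nonredundant(
            p for p in mapped
            if p.replicon_id == call.replicon_id
            and supports(p, call, lengths[call.replicon_id])
        )
        if len(confirming) < min_support:
            continue
        out.append(
            ErrorCall("missed", calls.caller_id, call.replicon_id, call.strand,
                      (call.start, call.end), tuple(confirming),
                      len(confirming), subject_call=None)
        )
    out.sort(key=lambda e: (e.replicon_id, e.implied_interval, e.category))
    return out


def joint_false_rate(per_peptide_fdr: float, k: int) -> float:
    """Probability that k independent supporting peptides are all false
    identifications: the product rule ``per_peptide_fdr ** k``.

    At the 0.3 % per-peptide FDR typical of large proteogenomic
    compilations, requiring two non-redundant peptides drives the joint
    rate to 9e-6.
    """
    if not 0.0 <= per_peptide_fdr <= 1.0:
        raise ValueError(f"per_peptide_fdr must be in [0, 1], got {per_peptide_fdr}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return per_peptide_fdr ** k


def tally_errors(
    errors: Sequence[ErrorCall],
    group_by: Sequence[str] = ("caller", "category"),
) -> pd.DataFrame:
    """Count errors per grouping of {caller, replicon, category}.

    Returns a tidy DataFrame with the grouping columns plus ``n``; the
    grand total always equals ``len(errors)``.
    """
    valid = {"caller", "replicon", "category"}
    cols = list(group_by)
    if not set(cols) <= valid:
        raise ValueError(f"group_by must be a subset of {sorted(valid)}")
    df = pd.DataFrame(
        {
            "caller": [e.caller_id for e in errors],
            "replicon": [e.replicon_id for e in errors],
            "category": [e.category for e in errors],
        }
    )
    if df.empty:
        return pd.DataFrame(columns=cols + ["n"])
    return (
        df.groupby(cols, as_index=False).size().rename(columns={"size": "n"})
        .sort_values(cols).reset_index(drop=True)
    )


def errors_to_frame(errors: Sequence[ErrorCall]) -> pd.DataFrame:
    """Flat error table (one row per error) for TSV export."""
    rows = []
    for e in errors:
        rows.append(
            {
                "category": e.category,
                "caller": e.caller_id,
                "replicon": e.replicon_id,
                "strand": e.strand,
                "subject_start": e.subject_call.start if e.subject_call else "",
                "subject_end": e.subject_call.end if e.subject_call else "",
                "implied_start": e.implied_interval[0],
                "implied_end": e.implied_interval[1],
                "n_nonredundant": e.n_nonredundant,
                "peptide_ids": ",".join(p.peptide_id for p in e.supporting_peptides),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "caller", "replicon", "strand", "subject_start",
                 "subject_end", "implied_start", "implied_end",
                 "n_nonredundant", "peptide_ids"],
    )
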