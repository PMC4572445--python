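"""Reading and writing gene-call sets (GFF3), peptide inputs, and
evaluation outputs.

Gene calls arrive as one GFF3 file per caller.  CDS features sharing a
``Parent`` (or, failing that, an ``ID`` / ``locus_tag``) are reassembled
into a single call with ordered fragments — the representation a
gene-finding post-processor uses for genes disrupted by frameshifts or
internal stops, where the coordinates of every CDS fragment are retained.
Pseudogene status is taken from a parent feature of type ``pseudogene``
or a ``pseudo=true`` attribute (both dialects accepted; the feature-type
form is emitted).

All in-memory coordinates are 0-based half-open; GFF3 files use 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

GFF3_HEADER = "##gff-version 3"


@dataclass(frozen=True)
class GeneCall:
    """One caller's predicted CDS.

    ``fragments`` has one interval for an ordinary call and several for a
    disrupted gene whose pieces were retained; fragments are ordered along
    the forward axis, non-overlapping, and lie within ``[start, end)``.
    A multi-fragment call without the pseudogene tag is an (untagged)
    frameshifted gene.
    """

    replicon_id: str
    strand: str
    start: int
    end: int
    caller_id: str
    is_pseudogene: bool = False
    fragments: tuple[tuple[int, int], ...] = ()
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.fragments:
            object.__setattr__(self, "fragments", ((self.start, self.end),))
        frs = tuple(sorted(self.fragments))
        object.__setattr__(self, "fragments", frs)
        if frs[0][0] < self.start or frs[-1][1] > self.end:
            raise ValueError("fragments extend outside the call interval")
        for (a0, a1), (b0, b1) in zip(frs, frs[1:]):
            if b0 < a1:
                raise ValueError("overlapping fragments")
        if sum(b - a for a, b in frs) < 3:
            raise ValueError("total fragment length < 3")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity used for caller-to-caller comparison."""
        return (self.replicon_id, self.strand, self.start, self.end)

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def fragment_frames(self, replicon_length: int) -> tuple[int, ...]:
        """Intrinsic frame of each fragment (strand-aware)."""
        if self.strand == "+":
            return tuple(a % 3 for a, _ in self.fragments)
        return tuple((replicon_length - b) % 3 for _, b in self.fragments)


class GeneCallSet:
    """All calls of one caller, indexed by replicon and interval."""

    def __init__(self, caller_id: str, calls: Iterable[GeneCall] = ()):
        self.caller_id = caller_id
        self.calls: list[GeneCall] = []
        self._trees: dict[str, IntervalTree] = {}
        self._keys: set[tuple] = set()
        for c in calls:
            self.add(c)

    def add(self, call: GeneCall) -> None:
        if call.key in self._keys:
            raise ValueError(f"duplicate gene call {call.key}")
        self._keys.add(call.key)
        self.calls.append(call)
        self._trees.setdefault(call.replicon_id, IntervalTree()).addi(
            call.start, call.end, call
        )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[GeneCall]:
        return iter(sorted(self.calls, key=lambda c: c.key))

    def overlapping(self, replicon_id: str, start: int, end: int) -> list[GeneCall]:
        tree = self._trees.get(replicon_id)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda c: c.key)

    def keys(self) -> set[tuple]:
        return set(self._keys)


@dataclass(frozen=True)
class PeptideInput:
    """An identified peptide sequence, optionally with pre-mapped
    coordinates (0-based half-open) from the upstream search pipeline."""

    peptide_id: str
    aa_seq: str
    replicon_id: str | None = None
    strand: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"peptide {self.peptide_id!r}: empty sequence")
        bad = set(self.aa_seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"peptide {self.peptide_id!r}: non-standard residue(s) "
                f"{sorted(bad)}"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.replicon_id is not None and self.start is not None


# ---------------------------------------------------------------------------
# GFF3 gene calls

def _truthy(values: list[str]) -> bool:
    return bool(values) and values[0].lower() in {"true", "1", "yes"}


def read_gene_calls(path: str | Path, caller_id: str) -> GeneCallSet:
    """Parse one caller's GFF3 into a :class:`GeneCallSet`.

    CDS rows sharing a Parent (else ID, else locus_tag) collapse into one
    multi-fragment call.  Raises on ``end < start`` (with the file line
    number) and on CDS rows with unknown strand.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 5:
                try:
                    lo, hi = int(cols[3]), int(cols[4])
                except ValueError:
                    continue
                if hi < lo:
                    raise ValueError(
                        f"{path.name} line {lineno}: end < start ({hi} < {lo})"
                    )

    if not any(
        l.strip() and not l.startswith("#") for l in path.read_text().splitlines()
    ):
        return GeneCallSet(caller_id)  # legitimately empty call set

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    parent_type: dict[str, str] = {}
    parent_pseudo: dict[str, bool] = {}
    for feat in db.all_features():
        if feat.featuretype != "CDS":
            fid = feat.attributes.get("ID", [feat.id])[0]
            parent_type[fid] = feat.featuretype
            parent_pseudo[fid] = feat.featuretype == "pseudogene" or _truthy(
                feat.attributes.get("pseudo", [])
            )

    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    for n, feat in enumerate(db.features_of_type("CDS")):
        if feat.strand not in "+-":
            raise ValueError(
                f"{path.name}: CDS {feat.id!r} has unknown strand {feat.strand!r}"
            )
        parents = feat.attributes.get("Parent", [])
        if parents:
            gkey = (feat.seqid, "parent", parents[0])
        elif feat.attributes.get("ID"):
            gkey = (feat.seqid, "id", feat.attributes["ID"][0])
        elif feat.attributes.get("locus_tag"):
            gkey = (feat.seqid, "locus", feat.attributes["locus_tag"][0])
        else:
            gkey = (feat.seqid, "anon", n)
        if gkey not in groups:
            groups[gkey] = []
            order.append(gkey)
        groups[gkey].append(feat)

    out = GeneCallSet(caller_id)
    for gkey in order:
        feats = groups[gkey]
        strand = feats[0].strand
        frags = tuple(sorted((f.start - 1, f.end) for f in feats))
        pseudo = any(_truthy(f.attributes.get("pseudo", [])) for f in feats)
        label = gkey[2] if gkey[1] != "anon" else f"{caller_id}_{gkey[2]}"
        if gkey[1] == "parent":
            pseudo = pseudo or parent_pseudo.get(gkey[2], False)
        out.add(
            GeneCall(
                replicon_id=feats[0].seqid,
                strand=strand,
                start=frags[0][0],
                end=frags[-1][1],
                caller_id=caller_id,
                is_pseudogene=pseudo,
                fragments=frags,
                call_id=str(label),
            )
        )
    return out


def write_gene_calls(calls: GeneCallSet, path: str | Path) -> None:
    """Emit a GeneCallSet as GFF3.  Single-fragment calls become one CDS
    row; disrupted calls become a parent (``pseudogene`` or ``gene``) row
    plus one CDS row per fragment."""
    lines = [GFF3_HEADER]
    for i, c in enumerate(calls):
        cid = c.call_id or f"{calls.caller_id}_{i:05d}"
        if len(c.fragments) == 1 and not c.is_pseudogene:
            lines.append(
                "\t".join(
                    [c.replicon_id, calls.caller_id, "CDS", str(c.start + 1),
                     str(c.end), ".", c.strand, "0", f"ID={cid}"]
                )
            )
            continue
        ptype = "pseudogene" if c.is_pseudogene else "gene"
        lines.append(
            "\t".join(
                [c.replicon_id, calls.caller_id, ptype, str(c.start + 1),
                 str(c.end), ".", c.strand, ".", f"ID={cid}"]
            )
        )
        for j, (a, b) in enumerate(c.fragments):
            lines.append(
                "\t".join(
                    [c.replicon_id, calls.caller_id, "CDS", str(a + 1), str(b),
                     ".", c.strand, "0", f"ID={cid}.c{j};Parent={cid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Peptides

def read_peptides(path: str | Path) -> list[PeptideInput]:
    """Read peptides from a TSV (columns ``peptide_id``, ``aa_seq``) or a
    GFF file whose peptide features carry a sequence attribute.

    File order is preserved and duplicate sequences are retained — each
    row is a distinct observation.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("peptide file %s is empty", path)
        return []
    first = next(l for l in text.splitlines() if l.strip())
    if first.startswith("##gff-version") or (
        len(first.split("\t")) == 9 and not first.lower().startswith("peptide_id")
    ):
        return _read_peptides_gff(path)
    return _read_peptides_tsv(path, text)


def _read_peptides_tsv(path: Path, text: str) -> list[PeptideInput]:
    rows = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = rows[0].lower().split("\t")
    try:
        id_col = header.index("peptide_id")
        seq_col = header.index("aa_seq")
    except ValueError as exc:
        raise ValueError(
            f"{path.name}: TSV must have 'peptide_id' and 'aa_seq' columns"
        ) from exc
    out = []
    for rowno, line in enumerate(rows[1:], 2):
        cols = line.split("\t")
        try:
            out.append(PeptideInput(cols[id_col], cols[seq_col]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path.name} row {rowno}: {exc}") from exc
    return out


_SEQ_ATTRS = ("Sequence", "sequence", "seq", "aa_seq")


def _read_peptides_gff(path: Path) -> list[PeptideInput]:
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for feat in db.all_features():
        if feat.featuretype not in {"polypeptide", "peptide"}:
            continue
        aa = None
        for attr in _SEQ_ATTRS:
            if feat.attributes.get(attr):
                aa = feat.attributes[attr][0]
                break
        if aa is None:
            raise ValueError(
                f"{path.name}: peptide feature {feat.id!r} lacks a sequence attribute"
            )
        pid = feat.attributes.get("ID", [feat.id])[0]
        out.append(
            PeptideInput(
                peptide_id=pid,
                aa_seq=aa,
                replicon_id=feat.seqid,
                strand=feat.strand if feat.strand in "+-" else None,
                start=feat.start - 1,
                end=feat.end,
            )
        )
    if not out:
        logger.warning("no peptide features found in %s", path)
    return out


def write_peptides_tsv(peptides: Sequence[PeptideInput], path: str | Path) -> None:
    lines = ["peptide_id\taa_seq"]
    lines += [f"{p.peptide_id}\t{p.aa_seq}" for p in peptides]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Conflict tracks

def write_conflict_gff(conflicts: Sequence, path: str | Path) -> None:
    """Write conflicting peptides as a GFF3 ``polypeptide`` track
    (one feature per conflict, relation and caller in the attributes)."""
    lines = [GFF3_HEADER]
    for rec in conflicts:
        p = rec.peptide
        attrs = (
            f"ID={p.peptide_id};relation={rec.relation};"
            f"caller_id={rec.caller_id};Sequence={p.aa_seq}"
        )
        lines.append(
            "\t".join(
                [p.replicon_id, "progeval", "polypeptide", str(p.start + 1),
                 str(p.end), ".", p.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_conflict_gff(path: str | Path) -> list[tuple[str, str, PeptideInput]]:
    """Round-trip reader for conflict tracks: returns
    ``(relation, caller_id, peptide-with-coordinates)`` tuples."""
    body = [l for l in Path(path).read_text().splitlines()
            if l.strip() and not l.startswith("#")]
    if not body:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for feat in db.features_of_type("polypeptide"):
        out.append(
            (
                feat.attributes["relation"][0],
                feat.attributes["caller_id"][0],
                PeptideInput(
                    peptide_id=feat.attributes["ID"][0],
                    aa_seq=feat.attributes["Sequence"][0],
                    replicon_id=feat.seqid,
                    strand=feat.strand,
                    start=feat.start - 1,
                    end=feat.end,
                ),
            )
        )
    return out
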