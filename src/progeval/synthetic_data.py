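"""Synthetic replicons, truth gene sets, caller-style perturbed call sets,
and tryptic peptide evidence.

The generator emulates the statistical structure the evaluation assumes:
prokaryotic replicons of tunable GC and length; non-overlapping
protein-coding genes on both strands (ATG start, single in-frame stop at
the 3' end, codon composition tuned toward the GC target); caller-specific
perturbations (start truncations, deleted genes, wrong-frame replacement
calls, pseudogene-tagged frameshift splits); and peptide evidence from an
in-silico tryptic digest with per-gene expression (default 40 % of genes
yield peptides) and a per-peptide false-match rate (default 0.3 %).

Every planted deviation is recorded in a ledger with its expected error
category, so downstream classification can be scored exactly.  All
randomness flows from a single integer seed; identical seeds produce
byte-identical benchmark bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Data import CodonTable
from pyteomics import parser as _pyt_parser

from .annotation_io import (
    GeneCall,
    GeneCallSet,
    PeptideInput,
    write_gene_calls,
    write_peptides_tsv,
)
from .sequence_core import FrameIndex, Replicon, revcomp, write_fasta

TRYPSIN_RULE = _pyt_parser.expasy_rules["trypsin"]
#: Length filter applied to in-silico tryptic peptides (aa).
DEFAULT_PEPTIDE_LEN_RANGE = (6, 50)
#: Planted errors require this many detectable peptides so that the
#: two-peptide evidence rule survives occasional ambiguity discards.
MIN_PLANT_PEPTIDES = 3

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class SimParams:
    """Replicon-level simulation parameters.

    Defaults reflect a mid-sized bacterial replicon at the panel-average
    GC of 57.7 %: 100 kb, 80 genes of mean length 900 nt (~300 aa,
    typical for bacteria), short intergenic spacers.
    """

    genome_length: int = 100_000
    gc_percent: float = 57.7
    n_genes: int = 80
    gene_length_dist: tuple[float, float] = (900.0, 200.0)
    intergenic_dist: tuple[float, float] = (150.0, 80.0)
    seed: int = 0
    replicon_id: str = "simrep"
    min_gene_length: int = 300
    min_intergenic: int = 30

    def __post_init__(self) -> None:
        if not 25.0 <= self.gc_percent <= 75.0:
            raise ValueError("gc_percent must be in [25, 75]")
        if self.n_genes * self.gene_length_dist[0] >= self.genome_length:
            raise ValueError(
                "n_genes * mean gene length must be < genome_length"
            )


@dataclass
class ErrorProfile:
    """Per-caller perturbation profile.

    Probability fields plant errors independently per gene; the exact
    ``n_*`` counts (when set) override them and plant precisely that many
    errors of each kind on randomly chosen eligible genes.
    """

    caller_id: str
    p_start_truncate: float = 0.0
    truncate_len_dist: tuple[float, float] = (90.0, 30.0)  # nt, forced to 3k
    p_miss_gene: float = 0.0
    p_spurious_wrong_frame: float = 0.0  # expected count per genome
    p_pseudogene_tag: float = 0.0
    p_untagged_frameshift: float = 0.0
    n_short: int | None = None
    n_missed: int | None = None
    n_wrong: int | None = None
    n_pseudogene_mistag: int | None = None
    n_untagged_frameshift: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_start_truncate, self.p_miss_gene,
                  self.p_pseudogene_tag, self.p_untagged_frameshift):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def count_mode(self) -> bool:
        return any(
            n is not None
            for n in (self.n_short, self.n_missed, self.n_wrong,
                      self.n_pseudogene_mistag, self.n_untagged_frameshift)
        )


@dataclass
class DetectionParams:
    """Peptide-evidence parameters: which genes are expressed, which
    tryptic peptides are detected, and the false-match rate."""

    p_gene_expressed: float = 0.4
    p_peptide_detected: float = 0.8
    peptide_len_range: tuple[int, int] = DEFAULT_PEPTIDE_LEN_RANGE
    false_match_rate: float = 0.003

    def __post_init__(self) -> None:
        for p in (self.p_gene_expressed, self.p_peptide_detected,
                  self.false_match_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.peptide_len_range[0] < 1:
            raise ValueError("peptide_len_range minimum must be >= 1")


@dataclass
class PlantedError:
    """One ledger entry: a deliberate deviation between truth and a
    perturbed call set, with the error category it should produce
    (None when the deviation should be scored as a good call)."""

    kind: str  # short | missed | wrong | pseudogene_mistag | untagged_frameshift
    expected_category: str | None
    caller_id: str
    replicon_id: str
    strand: str
    truth_start: int
    truth_end: int
    call_start: int | None = None
    call_end: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Digestion

def tryptic_digest(protein: str) -> list[tuple[int, str]]:
    """Cleave after K or R, not before P (expasy trypsin rule).

    Returns ``(aa_start, peptide)`` pairs in sequence order, unfiltered.
    """
    return sorted((s, p) for s, p in _pyt_parser.icleave(protein, TRYPSIN_RULE))


def _filtered_digest(protein: str,
                     len_range: tuple[int, int]) -> list[tuple[int, str]]:
    lo, hi = len_range
    return [(s, p) for s, p in tryptic_digest(protein) if lo <= len(p) <= hi]


# ---------------------------------------------------------------------------
# Replicon simulation

def _codon_weights(gc_fraction: float) -> tuple[list[str], np.ndarray]:
    table = CodonTable.unambiguous_dna_by_id[11]
    codons = sorted(table.forward_table)
    pbase = {
        "G": gc_fraction / 2, "C": gc_fraction / 2,
        "A": (1 - gc_fraction) / 2, "T": (1 - gc_fraction) / 2,
    }
    w = np.array([np.prod([pbase[b] for b in c]) for c in codons])
    return codons, w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> str:
    probs = [gc_fraction / 2, gc_fraction / 2,
             (1 - gc_fraction) / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list("GCAT"), size=n, p=probs))


def simulate_replicon(params: SimParams) -> tuple[Replicon, GeneCallSet]:
    """Generate a replicon and its truth gene set.

    Genes are placed non-overlapping on both strands, each ATG-initiated
    with its only in-frame stop at the 3' end; codon usage is biased
    toward the GC target so coding regions stay stop-free without
    drifting the overall composition.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    gcf = params.gc_percent / 100.0
    codons, cw = _codon_weights(gcf)
    stop_w = np.array([np.prod([{
        "G": gcf / 2, "C": gcf / 2, "A": (1 - gcf) / 2, "T": (1 - gcf) / 2
    }[b] for b in c]) for c in STOP_CODONS])
    stop_w = stop_w / stop_w.sum()

    mean_len, sd_len = params.gene_length_dist
    lengths = []
    for _ in range(params.n_genes):
        glen = int(round(rng.normal(mean_len, sd_len) / 3)) * 3
        lengths.append(max(params.min_gene_length, glen))
    mean_gap, sd_gap = params.intergenic_dist
    gaps = [
        max(params.min_intergenic, int(round(rng.normal(mean_gap, sd_gap))))
        for _ in range(params.n_genes)
    ]
    body = sum(lengths) + sum(gaps)
    if body > params.genome_length:
        raise ValueError(
            f"cannot pack {params.n_genes} genes into {params.genome_length} nt; "
            "reduce n_genes or gene/intergenic lengths"
        )

    pieces: list[str] = []
    truth = GeneCallSet("truth")
    pos = 0
    for i, (glen, gap) in enumerate(zip(lengths, gaps)):
        pieces.append(_random_bases(rng, gap, gcf))
        pos += gap
        n_codons = glen // 3 - 2
        coding = "ATG" + "".join(rng.choice(codons, size=n_codons, p=cw))
        coding += str(rng.choice(list(STOP_CODONS), p=stop_w))
        strand = "+" if rng.random() < 0.5 else "-"
        pieces.append(coding if strand == "+" else revcomp(coding))
        truth.add(
            GeneCall(params.replicon_id, strand, pos, pos + glen,
                     caller_id="truth", call_id=f"gene{i:04d}")
        )
        pos += glen
    if pos < params.genome_length:
        pieces.append(_random_bases(rng, params.genome_length - pos, gcf))
    replicon = Replicon(params.replicon_id, "".join(pieces))
    return replicon, truth


# ---------------------------------------------------------------------------
# Call-set perturbation

def _gene_protein(call: GeneCall, replicon: Replicon) -> str:
    nt = replicon.seq[call.start : call.end]
    if call.strand == "-":
        nt = revcomp(nt)
    nt = nt[:-3]  # drop the stop codon
    from .sequence_core import _translate_oriented

    return _translate_oriented(nt, 11)


def _truncate_candidates(call: GeneCall, protein: str,
                         len_range: tuple[int, int],
                         min_remaining_nt: int = 150) -> tuple[int, int] | None:
    """Valid range (inclusive) of in-frame truncation cuts, in aa, such
    that >= MIN_PLANT_PEPTIDES filtered peptides start upstream of the cut
    and the truncated call keeps ``min_remaining_nt``."""
    starts = sorted(s for s, _ in _filtered_digest(protein, len_range))
    if len(starts) < MIN_PLANT_PEPTIDES + 1:
        return None
    lo = max(starts[MIN_PLANT_PEPTIDES - 1] + 1, 3)
    hi = (call.end - call.start - min_remaining_nt) // 3
    if lo > hi:
        return None
    return lo, hi


def _apply_truncation(call: GeneCall, cut_aa: int) -> GeneCall:
    if call.strand == "+":
        return GeneCall(call.replicon_id, "+", call.start + 3 * cut_aa,
                        call.end, call.caller_id, call_id=call.call_id)
    return GeneCall(call.replicon_id, "-", call.start,
                    call.end - 3 * cut_aa, call.caller_id, call_id=call.call_id)


def _wrong_frame_call(call: GeneCall, rng: np.random.Generator) -> GeneCall:
    shift = int(rng.integers(1, 3))
    glen = call.end - call.start
    new_start = call.start + shift
    new_end = new_start + 3 * ((glen - shift) // 3)
    return GeneCall(call.replicon_id, call.strand, new_start, new_end,
                    call.caller_id, call_id=call.call_id + "_wf")


def _split_fragments(call: GeneCall, protein: str,
                     len_range: tuple[int, int],
                     rng: np.random.Generator) -> tuple[tuple[int, int], ...] | None:
    """Split a call into two fragments separated by a 3 nt in-frame gap,
    emulating retained CDS pieces of a disrupted gene."""
    n_aa = (call.end - call.start) // 3 - 1
    if n_aa < 40:
        return None
    cut = int(rng.integers(n_aa // 3, 2 * n_aa // 3))
    gpos = call.start + 3 * cut
    return ((call.start, gpos), (gpos + 3, call.end))


def perturb_calls(
    truth: GeneCallSet,
    profile: ErrorProfile,
    replicon: Replicon,
    seed: int,
    len_range: tuple[int, int] = DEFAULT_PEPTIDE_LEN_RANGE,
) -> tuple[GeneCallSet, list[PlantedError]]:
    """Derive one caller's call set from truth by planting errors.

    Returns the perturbed set plus a complete ledger: every deviation
    appears with its expected downstream category.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth, key=lambda c: c.key)
    out = GeneCallSet(profile.caller_id)
    ledger: list[PlantedError] = []

    plan: dict[tuple, str] = {}
    if profile.count_mode:
        proteins = {g.key: _gene_protein(g, replicon) for g in genes}
        eligible = [
            g for g in genes
            if len(_filtered_digest(proteins[g.key], len_range)) >= MIN_PLANT_PEPTIDES
        ]
        short_ok = [
            g for g in eligible
            if _truncate_candidates(g, proteins[g.key], len_range) is not None
        ]
        split_ok = [g for g in eligible if (g.end - g.start) // 3 - 1 >= 40]
        wanted = [
            ("short", profile.n_short or 0, short_ok),
            ("missed", profile.n_missed or 0, eligible),
            ("wrong", profile.n_wrong or 0, eligible),
            ("pseudogene_mistag", profile.n_pseudogene_mistag or 0, split_ok),
            ("untagged_frameshift", profile.n_untagged_frameshift or 0, split_ok),
        ]
        taken: set[tuple] = set()
        for kind, n, pool in wanted:
            avail = [g for g in pool if g.key not in taken]
            if n > len(avail):
                raise ValueError(
                    f"{profile.caller_id}: cannot plant {n} {kind} errors; "
                    f"only {len(avail)} eligible genes remain"
                )
            picks = rng.choice(len(avail), size=n, replace=False) if n else []
            for i in sorted(int(j) for j in picks):
                plan[avail[i].key] = kind
                taken.add(avail[i].key)

    proteins_cache: dict[tuple, str] = {}

    def protein_of(g: GeneCall) -> str:
        if g.key not in proteins_cache:
            proteins_cache[g.key] = _gene_protein(g, replicon)
        return proteins_cache[g.key]

    n_wrong_prob = (
        rng.poisson(profile.p_spurious_wrong_frame)
        if not profile.count_mode and profile.p_spurious_wrong_frame > 0 else 0
    )
    wrong_prob_keys: set[tuple] = set()
    if n_wrong_prob:
        picks = rng.choice(len(genes), size=min(n_wrong_prob, len(genes)),
                           replace=False)
        wrong_prob_keys = {genes[int(i)].key for i in picks}

    for g in genes:
        if profile.count_mode:
            kind = plan.get(g.key)
        else:
            u = rng.random()
            if u < profile.p_miss_gene:
                kind = "missed"
            elif u < profile.p_miss_gene + profile.p_start_truncate:
                kind = "short"
            elif g.key in wrong_prob_keys:
                kind = "wrong"
            elif rng.random() < profile.p_pseudogene_tag:
                kind = "pseudogene_mistag"
            elif rng.random() < profile.p_untagged_frameshift:
                kind = "untagged_frameshift"
            else:
                kind = None

        if kind is None:
            out.add(GeneCall(g.replicon_id, g.strand, g.start, g.end,
                             profile.caller_id, call_id=g.call_id))
            continue

        if kind == "missed":
            ledger.append(PlantedError("missed", "missed", profile.caller_id,
                                       g.replicon_id, g.strand, g.start, g.end))
            continue

        if kind == "short":
            cand = _truncate_candidates(g, protein_of(g), len_range)
            if cand is None:  # probability mode may pick an ineligible gene
                out.add(GeneCall(g.replicon_id, g.strand, g.start, g.end,
                                 profile.caller_id, call_id=g.call_id))
                continue
            lo, hi = cand
            mean_cut = profile.truncate_len_dist[0] / 3.0
            sd_cut = max(profile.truncate_len_dist[1] / 3.0, 1.0)
            cut = int(np.clip(round(rng.normal(mean_cut, sd_cut)), lo, hi))
            newc = _apply_truncation(g, cut)
            out.add(GeneCall(newc.replicon_id, newc.strand, newc.start,
                             newc.end, profile.caller_id, call_id=g.call_id))
            ledger.append(PlantedError("short", "short", profile.caller_id,
                                       g.replicon_id, g.strand, g.start, g.end,
                                       newc.start, newc.end))
            continue

        if kind == "wrong":
            newc = _wrong_frame_call(g, rng)
            out.add(GeneCall(newc.replicon_id, newc.strand, newc.start,
                             newc.end, profile.caller_id, call_id=newc.call_id))
            ledger.append(PlantedError("wrong", "wrong", profile.caller_id,
                                       g.replicon_id, g.strand, g.start, g.end,
                                       newc.start, newc.end))
            continue

        # frameshift splits (tagged or untagged)
        frags = _split_fragments(g, protein_of(g), len_range, rng)
        if frags is None:
            out.add(GeneCall(g.replicon_id, g.strand, g.start, g.end,
                             profile.caller_id, call_id=g.call_id))
            continue
        tagged = kind == "pseudogene_mistag"
        out.add(
            GeneCall(g.replicon_id, g.strand, g.start, g.end,
                     profile.caller_id, is_pseudogene=tagged,
                     fragments=frags, call_id=g.call_id + "_fs")
        )
        ledger.append(
            PlantedError(kind, "missed" if tagged else None,
                         profile.caller_id, g.replicon_id, g.strand,
                         g.start, g.end, g.start, g.end)
        )

    return out, ledger


# ---------------------------------------------------------------------------
# Peptide evidence

def _false_peptide(
    rng: np.random.Generator,
    index: FrameIndex,
    truth: GeneCallSet,
    replicon: Replicon,
    len_range: tuple[int, int],
    max_tries: int = 200,
) -> tuple[str, dict] | None:
    """A decoy peptide taken from a non-coding or wrong-frame region,
    rejection-sampled to map uniquely — it exercises the false-discovery
    pathway, not the ambiguity discard."""
    keys = sorted(index.frames)
    lo = max(len_range[0], 8)
    hi = min(len_range[1], 15)
    for _ in range(max_tries):
        key = keys[int(rng.integers(len(keys)))]
        ft = index.frames[key]
        plen = int(rng.integers(lo, hi + 1))
        if len(ft.aa_seq) <= plen:
            continue
        pos = int(rng.integers(0, len(ft.aa_seq) - plen))
        cand = ft.aa_seq[pos : pos + plen]
        if "*" in cand or "X" in cand:
            continue
        gstart, gend = ft.genomic_interval(pos, pos + plen)
        # must not be an in-frame substring of a real gene product
        in_gene = any(
            c.strand == ft.strand and c.start <= gstart and gend <= c.end
            and (c.start % 3 if c.strand == "+" else (replicon.length - c.end) % 3)
            == ft.frame
            for c in truth.overlapping(replicon.id, gstart, gend)
        )
        if in_gene:
            continue
        n_hits = sum(1 for k in keys if cand in index.frames[k].aa_seq)
        if n_hits != 1 or index.frames[key].aa_seq.count(cand) != 1:
            continue
        return cand, {
            "replicon": replicon.id, "strand": ft.strand,
            "start": gstart, "end": gend, "frame": ft.frame,
            "gene_id": None, "false": True,
        }
    return None


def sample_peptides(
    truth: GeneCallSet,
    replicon: Replicon,
    det: DetectionParams,
    seed: int,
) -> tuple[list[PeptideInput], dict[str, dict]]:
    """Generate peptide evidence from expressed truth genes.

    Per gene: expressed with probability ``p_gene_expressed``; its protein
    is digested with trypsin, length-filtered, and each peptide is emitted
    with probability ``p_peptide_detected``.  Each emission additionally
    spawns a decoy false peptide with probability ``false_match_rate``.
    The ledger maps every peptide id to its true genomic locus.
    """
    rng = np.random.default_rng(seed)
    index: FrameIndex | None = None
    peptides: list[PeptideInput] = []
    ledger: dict[str, dict] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"pep{counter:06d}"

    for g in sorted(truth, key=lambda c: c.key):
        if rng.random() >= det.p_gene_expressed:
            continue
        protein = _gene_protein(g, replicon)
        for aa_start, pep in _filtered_digest(protein, det.peptide_len_range):
            if rng.random() >= det.p_peptide_detected:
                continue
            aa_end = aa_start + len(pep)
            if g.strand == "+":
                gstart, gend = g.start + 3 * aa_start, g.start + 3 * aa_end
            else:
                gstart, gend = g.end - 3 * aa_end, g.end - 3 * aa_start
            pid = next_id()
            peptides.append(PeptideInput(pid, pep))
            ledger[pid] = {
                "replicon": g.replicon_id, "strand": g.strand,
                "start": gstart, "end": gend,
                "frame": (gstart % 3 if g.strand == "+"
                          else (replicon.length - gend) % 3),
                "gene_id": g.call_id, "false": False,
            }
            if det.false_match_rate and rng.random() < det.false_match_rate:
                if index is None:
                    index = FrameIndex([replicon])
                fp = _false_peptide(rng, index, truth, replicon,
                                    det.peptide_len_range)
                if fp is not None:
                    fpid = next_id()
                    peptides.append(PeptideInput(fpid, fp[0]))
                    ledger[fpid] = fp[1]
    return peptides, ledger


# ---------------------------------------------------------------------------
# Benchmark bundles

@dataclass
class Benchmark:
    """A self-contained fixture: genome, truth, perturbed call sets,
    peptide evidence, and the planted-error / peptide-truth ledgers."""

    out_dir: Path
    replicon: Replicon
    truth: GeneCallSet
    call_sets: dict[str, GeneCallSet]
    peptides: list[PeptideInput]
    planted: list[PlantedError]
    peptide_truth: dict[str, dict]
    genome_path: Path = field(init=False)
    peptide_path: Path = field(init=False)
    call_paths: dict[str, Path] = field(init=False)

    def __post_init__(self) -> None:
        self.genome_path = self.out_dir / "genome.fasta"
        self.peptide_path = self.out_dir / "peptides.tsv"
        self.call_paths = {
            cid: self.out_dir / f"calls_{cid}.gff3" for cid in self.call_sets
        }


def make_benchmark(
    params: SimParams,
    profiles: Sequence[ErrorProfile],
    det: DetectionParams,
    seed: int,
    out_dir: str | Path,
) -> Benchmark:
    """Simulate, perturb, digest, and write a complete benchmark bundle.

    Re-running with the same seed reproduces the directory byte for byte.
    """
    if not profiles:
        raise ValueError("need at least one error profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = SimParams(**{**asdict(params), "seed": seed})
    replicon, truth = simulate_replicon(sim)
    call_sets: dict[str, GeneCallSet] = {}
    planted: list[PlantedError] = []
    for i, profile in enumerate(profiles):
        cs, ledger = perturb_calls(truth, profile, replicon,
                                   seed=seed + 1000 * (i + 1))
        call_sets[profile.caller_id] = cs
        planted.extend(ledger)
    peptides, pep_truth = sample_peptides(truth, replicon, det, seed=seed + 500)

    write_fasta([replicon], out_dir / "genome.fasta")
    write_gene_calls(truth, out_dir / "truth.gff3")
    for cid, cs in call_sets.items():
        write_gene_calls(cs, out_dir / f"calls_{cid}.gff3")
    write_peptides_tsv(peptides, out_dir / "peptides.tsv")
    (out_dir / "planted_errors.json").write_text(
        json.dumps([p.to_dict() for p in planted], indent=1, sort_keys=True)
        + "\n"
    )
    lines = ["peptide_id\treplicon\tstrand\tstart\tend\tframe\tgene_id\tfalse"]
    for pid in sorted(pep_truth):
        t = pep_truth[pid]
        lines.append(
            f"{pid}\t{t['replicon']}\t{t['strand']}\t{t['start']}\t{t['end']}"
            f"\t{t['frame']}\t{t['gene_id'] or '.'}\t{int(t['false'])}"
        )
    (out_dir / "peptide_truth.tsv").write_text("\n".join(lines) + "\n")

    return Benchmark(out_dir, replicon, truth, call_sets, peptides, planted,
                     pep_truth)


# ---------------------------------------------------------------------------
# Scoring against the ledger

def _matches_planted(error, planted: PlantedError) -> bool:
    if error.caller_id != planted.caller_id:
        return False
    if error.replicon_id != planted.replicon_id or error.strand != planted.strand:
        return False
    if planted.kind in ("short", "wrong"):
        # the contradicted call must be the planted perturbed call
        sc = error.subject_call
        return (sc is not None and sc.start == planted.call_start
                and sc.end == planted.call_end)
    # missed (deleted gene) and mistagged pseudogene: the implied gene
    # must cover the bulk of the truth gene
    lo = max(error.implied_interval[0], planted.truth_start)
    hi = min(error.implied_interval[1], planted.truth_end)
    return hi - lo >= (planted.truth_end - planted.truth_start) // 2


def score_against_ledger(errors, planted: Sequence[PlantedError]) -> dict:
    """Per-category precision/recall of classified errors against the
    planted-error ledger.

    A predicted error is a true positive when its category equals a
    planted entry's expected category and it points at the planted locus;
    planted entries with ``expected_category=None`` must produce nothing.
    """
    cats = ("wrong", "short", "missed")
    out: dict = {}
    expected = [p for p in planted if p.expected_category]
    for cat in cats:
        preds = [e for e in errors if e.category == cat]
        plants = [p for p in expected if p.expected_category == cat]
        matched_p: set[int] = set()
        tp = 0
        for e in preds:
            hit = next(
                (i for i, p in enumerate(plants)
                 if i not in matched_p and _matches_planted(e, p)),
                None,
            )
            if hit is None:
                continue
            matched_p.add(hit)
            tp += 1
        fp = len(preds) - tp
        fn = len(plants) - tp
        out[cat] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / len(preds) if preds else 1.0,
            "recall": tp / len(plants) if plants else 1.0,
        }
    return out


# ---------------------------------------------------------------------------
# Config

def load_config(path: str | Path) -> tuple[SimParams, list[ErrorProfile], DetectionParams]:
    """Read SimParams / ErrorProfiles / DetectionParams from one YAML file.

    Schema: top-level keys ``simulation``, ``callers`` (list of error
    profiles, each with a ``caller_id``), and ``detection``; unknown keys
    raise.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - {"simulation", "callers", "detection"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    def _tupled(d: dict, keys: Sequence[str]) -> dict:
        return {k: tuple(v) if k in keys and v is not None else v
                for k, v in d.items()}

    sim = SimParams(**_tupled(cfg.get("simulation", {}),
                              ("gene_length_dist", "intergenic_dist")))
    profiles = [
        ErrorProfile(**_tupled(p, ("truncate_len_dist",)))
        for p in cfg.get("callers", [])
    ]
    det = DetectionParams(**_tupled(cfg.get("detection", {}),
                                    ("peptide_len_range",)))
    return sim, profiles, det
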