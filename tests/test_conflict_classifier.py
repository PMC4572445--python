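"""Support/conflict partition and wrong/short/missed classification."""

import collections

import numpy as np
import pytest

from progeval.annotation_io import GeneCall, GeneCallSet
from progeval.conflict_classifier import (
    classify_errors,
    find_conflicts,
    joint_false_rate,
    peptide_support,
    rescore_pseudogenes,
    supports,
    tally_errors,
)
from progeval.peptide_mapper import MappedPeptide, map_all
from progeval.sequence_core import FrameIndex, Replicon, revcomp
from progeval.synthetic_data import (
    DetectionParams,
    ErrorProfile,
    SimParams,
    perturb_calls,
    sample_peptides,
    score_against_ledger,
    simulate_replicon,
)


def _pep(pid, start, end, strand="+", rid="r", L=None):
    frame = start % 3 if strand == "+" else (L - end) % 3
    return MappedPeptide(pid, "A" * ((end - start) // 3), rid, strand,
                         start, end, frame)


def _genome(n=3000):
    # all-codon 'GCT' backbone: no stops anywhere in frame 0 of '+'
    return Replicon("r", "GCT" * (n // 3))


def test_contained_in_frame_peptide_supports():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 0, 300, "c")])
    peps = [_pep("p", 90, 120)]
    s = peptide_support(peps, calls, [rep])
    assert s.n_supporting_peptides == 1
    assert s.coverage_percent == 100.0


def test_contained_wrong_strand_peptide_conflicts():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 0, 300, "c")])
    peps = [_pep("p", 90, 120, strand="-", L=rep.length)]
    s = peptide_support(peps, calls, [rep])
    assert s.n_supporting_peptides == 0
    conf = find_conflicts(peps, calls, [rep])
    assert len(conf) == 1


def test_empty_call_set_all_conflicting():
    rep = _genome()
    calls = GeneCallSet("c")
    peps = [_pep("p", 90, 120)]
    s = peptide_support(peps, calls, [rep])
    assert s.n_genes_total == 0 and s.coverage_percent == 0.0
    assert s.n_conflicting_peptides == 1


def test_conflict_relations():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 399, "c")])
    # frame-0 peptide over a frame-1 call (99 % 3 == 0 -> use frame-2 call)
    calls2 = GeneCallSet("c", [GeneCall("r", "+", 100, 400, "c")])
    out_of_frame = _pep("oof", 90, 120)  # frame 0 vs call frame 1
    conf = find_conflicts([out_of_frame], calls2, [rep])
    assert conf[0].relation == "overlaps_out_of_frame"

    upstream = _pep("up", 69, 129)  # in frame with call start 99, extends 5'
    conf = find_conflicts([upstream], calls, [rep])
    assert conf[0].relation == "extends_upstream"

    downstream = _pep("dn", 390, 420)  # in frame, past the 3' end
    conf = find_conflicts([downstream], calls, [rep])
    assert conf[0].relation == "spans_boundary"

    lone = _pep("far", 2400, 2430)
    conf = find_conflicts([lone], GeneCallSet("c", [GeneCall("r", "+", 99, 198, "c")]),
                          [rep])
    assert conf[0].relation == "outside_all"


def test_fully_upstream_in_orf_peptide_feeds_short_not_missed():
    """A peptide 5' of a call with no in-frame stop in between contradicts
    that call's start even without overlapping it."""
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 399, "c")])
    peps = [_pep("a", 60, 90), _pep("b", 75, 105)]
    conf = find_conflicts(peps, calls, [rep])
    assert {c.relation for c in conf} == {"extends_upstream"}
    errs = classify_errors(conf, calls, [rep])
    assert [e.category for e in errs] == ["short"]
    assert errs[0].implied_interval[0] == 60


def test_short_call_scored_with_implied_start():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 399, "c")])
    peps = [_pep("a", 69, 129), _pep("b", 84, 120)]
    conf = find_conflicts(peps, calls, [rep])
    errs = classify_errors(conf, calls, [rep])
    assert len(errs) == 1
    e = errs[0]
    assert e.category == "short"
    assert e.subject_call.key == ("r", "+", 99, 399)
    assert e.implied_interval == (69, 399)
    assert e.n_nonredundant == 2


def test_upstream_peptide_beyond_in_frame_stop_not_counted():
    # stop codon TAA at [60,63) in frame 0 separates far peptide from start
    seq = "GCT" * 20 + "TAA" + "GCT" * 500
    rep = Replicon("r", seq)
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 399, "c")])
    near = _pep("near", 63, 99)
    far = _pep("far", 30, 60)
    conf = find_conflicts([near, far], calls, [rep])
    errs = classify_errors(conf, calls, [rep])
    assert errs == []  # only one peptide inside the ORF extension


def test_nonredundancy_same_interval_counts_once():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 198, "c")])
    twice = [_pep("a", 2400, 2430), _pep("b", 2400, 2430)]
    conf = find_conflicts(twice, calls, [rep])
    errs = classify_errors(conf, calls, [rep])
    assert errs == []  # one distinct interval < min_support


def test_missed_gene_from_two_distinct_intervals():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 99, 198, "c")])
    peps = [_pep("a", 2400, 2430), _pep("b", 2415, 2445)]
    conf = find_conflicts(peps, calls, [rep])
    errs = classify_errors(conf, calls, [rep])
    assert [e.category for e in errs] == ["missed"]
    a, b = errs[0].implied_interval
    assert a <= 2400 and b >= 2445  # maximal-ORF implied gene


def test_wrong_call_needs_shared_peptide_frame():
    rep = _genome()
    calls = GeneCallSet("c", [GeneCall("r", "+", 100, 400, "c")])
    same_frame = [_pep("a", 90, 120), _pep("b", 120, 150)]
    conf = find_conflicts(same_frame, calls, [rep])
    errs = classify_errors(conf, calls, [rep])
    assert [e.category for e in errs] == ["wrong"]
    assert errs[0].subject_call.key == ("r", "+", 100, 400)

    mixed = [_pep("a", 90, 120), _pep("b", 121, 151)]  # frames 0 and 1
    conf = find_conflicts(mixed, calls, [rep])
    assert classify_errors(conf, calls, [rep]) == []


def test_min_support_validation():
    rep = _genome()
    with pytest.raises(ValueError):
        classify_errors([], GeneCallSet("c"), [rep], min_support=0)


# ---------------------------------------------------------------------------
# Pseudogene re-scoring

def _split_call(tagged):
    return GeneCall("r", "+", 99, 399, "c", is_pseudogene=tagged,
                    fragments=((99, 198), (201, 300), (303, 399)))


def test_pseudogene_with_confirming_peptides_scored_missed():
    rep = _genome()
    calls = GeneCallSet("c", [_split_call(tagged=True)])
    peps = [_pep("a", 102, 132), _pep("b", 231, 261)]  # two fragments
    assert all(supports(p, calls.calls[0], rep.length) for p in peps)
    errs = rescore_pseudogenes([], calls, peps, [rep])
    assert [e.category for e in errs] == ["missed"]
    assert errs[0].implied_interval == (99, 399)


def test_untagged_frameshift_with_peptides_is_good_call():
    rep = _genome()
    calls = GeneCallSet("c", [_split_call(tagged=False)])
    peps = [_pep("a", 102, 132), _pep("b", 231, 261)]
    assert rescore_pseudogenes([], calls, peps, [rep]) == []


def test_pseudogene_below_support_threshold_not_rescored():
    rep = _genome()
    calls = GeneCallSet("c", [_split_call(tagged=True)])
    errs = rescore_pseudogenes([], calls, [_pep("a", 102, 132)], [rep])
    assert errs == []


# ---------------------------------------------------------------------------
# FDR arithmetic and tallies

@pytest.mark.parametrize(
    "fdr,k,expect",
    [(0.003, 1, 0.003), (0.003, 2, 9e-6), (0.0, 5, 0.0), (1.0, 5, 1.0)],
)
def test_joint_false_rate_product_rule(fdr, k, expect):
    assert joint_false_rate(fdr, k) == pytest.approx(expect)


@pytest.mark.parametrize("fdr,k", [(-0.1, 1), (1.1, 1), (0.3, 0)])
def test_joint_false_rate_rejects_bad_input(fdr, k):
    with pytest.raises(ValueError):
        joint_false_rate(fdr, k)


def test_tally_marginals(noiseless_bench, noiseless_mapped):
    bench = noiseless_bench
    index, mapped, _ = noiseless_mapped
    calls = bench.call_sets["callerA"]
    errs = classify_errors(find_conflicts(mapped, calls, index), calls, index)
    errs = rescore_pseudogenes(errs, calls, mapped, index)
    by_cat = tally_errors(errs, ("category",))
    by_caller = tally_errors(errs, ("caller",))
    assert by_cat["n"].sum() == by_caller["n"].sum() == len(errs)
    assert tally_errors([], ("category",)).empty


# ---------------------------------------------------------------------------
# Planted-truth recovery and the partition invariant

def test_planted_errors_recovered_exactly(noiseless_bench, noiseless_mapped):
    bench = noiseless_bench
    index, mapped, _ = noiseless_mapped
    calls = bench.call_sets["callerA"]
    conf = find_conflicts(mapped, calls, index)
    errs = classify_errors(conf, calls, index)
    errs = rescore_pseudogenes(errs, calls, mapped, index)
    scores = score_against_ledger(errs, bench.planted)
    for cat in ("wrong", "short", "missed"):
        assert scores[cat]["precision"] == 1.0, (cat, scores[cat])
        assert scores[cat]["recall"] == 1.0, (cat, scores[cat])


def test_support_conflict_partition(noiseless_bench, noiseless_mapped):
    bench = noiseless_bench
    index, mapped, _ = noiseless_mapped
    for calls in (bench.truth, bench.call_sets["callerA"]):
        s = peptide_support(mapped, calls, index)
        conf = find_conflicts(mapped, calls, index)
        assert s.n_supporting_peptides + len(conf) == len(mapped)
        assert s.n_conflicting_peptides == len(conf)


def test_category_exclusivity(noiseless_bench, noiseless_mapped):
    """No peptide contributes to two errors of different categories
    against the same caller."""
    bench = noiseless_bench
    index, mapped, _ = noiseless_mapped
    calls = bench.call_sets["callerA"]
    errs = classify_errors(find_conflicts(mapped, calls, index), calls, index)
    errs = rescore_pseudogenes(errs, calls, mapped, index)
    seen: dict[str, set] = collections.defaultdict(set)
    for e in errs:
        for p in e.supporting_peptides:
            seen[p.peptide_id].add(e.category)
    assert all(len(cats) == 1 for cats in seen.values())


def test_classification_matches_naive_rule_oracle():
    """On a small instance with single-fragment calls, classification
    equals an exhaustive, independent evaluation of the scoring rules."""
    params = SimParams(genome_length=12_000, n_genes=8,
                       gene_length_dist=(600.0, 100.0), seed=13)
    replicon, truth = simulate_replicon(params)
    profile = ErrorProfile("c", n_short=2, n_missed=2, n_wrong=2)
    calls, _ = perturb_calls(truth, profile, replicon, seed=5)
    det = DetectionParams(p_gene_expressed=1.0, p_peptide_detected=1.0,
                          false_match_rate=0.0)
    peptides, _ = sample_peptides(truth, replicon, det, seed=3)
    mapped, _ = map_all(peptides, [replicon])
    errs = classify_errors(find_conflicts(mapped, calls, [replicon]),
                           calls, [replicon])
    got = {(e.category, e.subject_call.key if e.subject_call else
            (e.replicon_id, e.strand, *e.implied_interval)) for e in errs}
    assert got == _naive_error_oracle(mapped, calls, replicon)


def _naive_error_oracle(mapped, calls, replicon):
    """Case-by-case scoring for single-fragment calls only: brute stop
    scan, no interval index, no shared code with the implementation."""
    L = replicon.length

    def frame_of(strand, start, end):
        return start % 3 if strand == "+" else (L - end) % 3

    def stops_between(strand, frame, lo, hi):
        # any in-frame stop codon within genomic [lo, hi)?
        for s in range(lo, hi - 2, 3):
            codon = replicon.seq[s : s + 3]
            if strand == "-":
                codon = revcomp(codon)
            if codon in ("TAA", "TAG", "TGA"):
                return True
        return False

    def orf_of(strand, frame, start, end):
        lo = start
        step_back = lo - 3
        while step_back >= 0 and not stops_between(strand, frame, step_back, step_back + 3):
            lo = step_back
            step_back -= 3
        hi = end
        while hi + 3 <= L and not stops_between(strand, frame, hi, hi + 3):
            hi += 3
        return (lo, hi)

    call_list = list(calls)
    supporting = set()
    for p in mapped:
        for c in call_list:
            if (p.strand == c.strand and c.start <= p.start and p.end <= c.end
                    and frame_of(c.strand, c.start, c.end) == p.frame):
                supporting.add(p.peptide_id)
    confl = [p for p in mapped if p.peptide_id not in supporting]

    expected = set()
    for c in call_list:
        cf = frame_of(c.strand, c.start, c.end)
        # wrong: overlapping peptides in one different frame
        groups = collections.defaultdict(set)
        for p in confl:
            if p.start < c.end and p.end > c.start and (
                    p.strand != c.strand or p.frame != cf):
                groups[(p.strand, p.frame)].add((p.start, p.end))
        for g, ivs in groups.items():
            if len(ivs) >= 2:
                expected.add(("wrong", c.key))
        # short: in-frame upstream peptides inside the ORF extension
        ups = set()
        for p in confl:
            if p.strand != c.strand or p.frame != cf:
                continue
            if c.strand == "+" and p.start < c.start:
                if not stops_between("+", cf, p.start, c.start):
                    ups.add((p.start, p.end))
            if c.strand == "-" and p.end > c.end:
                if not stops_between("-", cf, c.end, p.end):
                    ups.add((p.start, p.end))
        if len(ups) >= 2:
            expected.add(("short", c.key))
    # missed: peptides overlapping no call, not upstream-in-ORF of one
    free = []
    for p in confl:
        if any(p.start < c.end and p.end > c.start for c in call_list):
            continue
        upstream = False
        for c in call_list:
            if p.strand != c.strand or p.frame != frame_of(c.strand, c.start, c.end):
                continue
            if c.strand == "+" and p.start < c.start and not stops_between(
                    "+", p.frame, p.start, c.start):
                upstream = True
            if c.strand == "-" and p.end > c.end and not stops_between(
                    "-", p.frame, c.end, p.end):
                upstream = True
        if not upstream:
            free.append(p)
    by_orf = collections.defaultdict(set)
    for p in free:
        orf = orf_of(p.strand, p.frame, p.start, p.end)
        by_orf[(p.strand, p.frame, orf)].add((p.start, p.end))
    for (strand, frame, orf), ivs in by_orf.items():
        if len(ivs) >= 2:
            expected.add(("missed", (replicon.id, strand, *orf)))
    return expected
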