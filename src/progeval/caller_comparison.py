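"""Consensus and disagreement statistics between gene-call sets.

Two calls are *identical* when replicon, strand, start and stop all
coincide; they *stop-agree* when they share the 3'-terminal coordinate on
the coding strand (end for '+', start for '-') but differ in start.  The
summary reports every overlap count under each caller's own denominator,
mirroring the dual-denominator percentages used when comparing ab initio
callers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .annotation_io import GeneCall, GeneCallSet


def _stop_key(call: GeneCall) -> tuple:
    stop = call.end if call.strand == "+" else call.start
    return (call.replicon_id, call.strand, stop)


def identical_genes(a: GeneCallSet, b: GeneCallSet) -> list[tuple[GeneCall, GeneCall]]:
    """Pairs of calls with equal (replicon, strand, start, end).

    Symmetric up to pair order; each call is matched at most once
    (call keys are unique within a set).
    """
    bmap = {c.key: c for c in b}
    return [(c, bmap[c.key]) for c in a if c.key in bmap]


def stop_agree_genes(a: GeneCallSet, b: GeneCallSet) -> list[tuple[GeneCall, GeneCall]]:
    """Pairs sharing the coding-strand stop but with different starts;
    disjoint from :func:`identical_genes` by construction.  When several
    calls in one set share a stop, leftover calls are paired greedily in
    coordinate order."""
    from collections import defaultdict

    a_by_stop: dict[tuple, list[GeneCall]] = defaultdict(list)
    b_by_stop: dict[tuple, list[GeneCall]] = defaultdict(list)
    for c in a:
        a_by_stop[_stop_key(c)].append(c)
    for c in b:
        b_by_stop[_stop_key(c)].append(c)
    pairs = []
    for sk in sorted(set(a_by_stop) & set(b_by_stop)):
        ca, cb = a_by_stop[sk], b_by_stop[sk]
        used_a, used_b = set(), set()
        # identical pairs are consumed first and excluded
        b_keys = {c.key: c for c in cb}
        for c in ca:
            if c.key in b_keys:
                used_a.add(c.key)
                used_b.add(c.key)
        rest_a = [c for c in ca if c.key not in used_a]
        rest_b = [c for c in cb if c.key not in used_b]
        pairs.extend(zip(rest_a, rest_b))
    return pairs


@dataclass
class ConsensusSummary:
    """All-way and pairwise agreement statistics for k >= 2 callers."""

    caller_ids: list[str]
    n_calls_per_caller: dict[str, int]
    n_identical_all: int
    n_identical_pairwise: dict[tuple[str, str], int]
    n_stop_agree_pairwise: dict[tuple[str, str], int]
    n_stop_consensus_all: int
    n_unique_per_caller: dict[str, int]
    #: 100 * n_identical_all / n_calls(c) for each caller c — the same
    #: numerator under each caller's own denominator.
    identical_all_percent: dict[str, float] = field(default_factory=dict)
    identical_pairwise_percent: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "caller_ids": self.caller_ids,
            "n_calls_per_caller": self.n_calls_per_caller,
            "n_identical_all": self.n_identical_all,
            "n_identical_pairwise": {
                "|".join(k): v for k, v in sorted(self.n_identical_pairwise.items())
            },
            "n_stop_agree_pairwise": {
                "|".join(k): v for k, v in sorted(self.n_stop_agree_pairwise.items())
            },
            "n_stop_consensus_all": self.n_stop_consensus_all,
            "n_unique_per_caller": self.n_unique_per_caller,
            "identical_all_percent": self.identical_all_percent,
            "identical_pairwise_percent": {
                "|".join(k): v
                for k, v in sorted(self.identical_pairwise_percent.items())
            },
        }


def consensus_summary(sets: Sequence[GeneCallSet]) -> ConsensusSummary:
    """Compute the full agreement summary for 2..k call sets.

    *Unique* calls are identical to a call in no other set.  The all-way
    identical set is by construction a subset of every pairwise identical
    set, and all counts are invariant under caller reordering.
    """
    if len(sets) < 2:
        raise ValueError("need at least two call sets")
    ids = [s.caller_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate caller_ids: {ids}")

    keysets = {s.caller_id: s.keys() for s in sets}
    stopsets = {s.caller_id: {_stop_key(c) for c in s} for s in sets}
    n_calls = {s.caller_id: len(s) for s in sets}

    ident_all = set.intersection(*keysets.values())
    stop_all = set.intersection(*stopsets.values())

    ident_pair: dict[tuple[str, str], int] = {}
    stop_pair: dict[tuple[str, str], int] = {}
    for sa, sb in itertools.combinations(sets, 2):
        pair = (sa.caller_id, sb.caller_id)
        ident_pair[pair] = len(identical_genes(sa, sb))
        stop_pair[pair] = len(stop_agree_genes(sa, sb))

    unique = {}
    for s in sets:
        others = set.union(*(keysets[c] for c in ids if c != s.caller_id))
        unique[s.caller_id] = len(keysets[s.caller_id] - others)

    def pct(n: int, caller: str) -> float:
        total = n_calls[caller]
        return 100.0 * n / total if total else 0.0

    summary = ConsensusSummary(
        caller_ids=ids,
        n_calls_per_caller=n_calls,
        n_identical_all=len(ident_all),
        n_identical_pairwise=ident_pair,
        n_stop_agree_pairwise=stop_pair,
        n_stop_consensus_all=len(stop_all),
        n_unique_per_caller=unique,
        identical_all_percent={c: pct(len(ident_all), c) for c in ids},
        identical_pairwise_percent={
            pair: {c: pct(n, c) for c in pair} for pair, n in ident_pair.items()
        },
    )
    return summary
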