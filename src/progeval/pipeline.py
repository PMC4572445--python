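"""End-to-end evaluation: map peptides, score support and coverage,
compare callers, classify errors, and emit the report bundle.

All outputs land under one run directory as flat TSV tables, GFF3
conflict tracks, and a single machine-readable ``summary.json`` whose
totals are consistent with every table written in the same run.  Given
identical inputs the bundle is byte-identical (no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .annotation_io import (
    GeneCallSet,
    read_gene_calls,
    read_peptides,
    write_conflict_gff,
)
from .caller_comparison import consensus_summary
from .conflict_classifier import (
    classify_errors,
    errors_to_frame,
    find_conflicts,
    joint_false_rate,
    peptide_support,
    rescore_pseudogenes,
    tally_errors,
)
from .peptide_mapper import map_all, write_mapping_tsv
from .sequence_core import FrameIndex, Replicon, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one evaluation run."""

    genome_path: str
    caller_gffs: dict[str, str]  # caller_id -> GFF3 path
    peptide_paths: list[str]
    out_dir: str
    min_support: int = 2
    per_peptide_fdr: float = 0.003
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not self.caller_gffs:
            raise ValueError("at least one caller is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            genome_path=cfg["genome"],
            caller_gffs=dict(cfg["callers"]),
            peptide_paths=list(cfg.get("peptides", [])),
            out_dir=cfg.get("out_dir", "progeval_run"),
            min_support=int(cfg.get("min_support", 2)),
            per_peptide_fdr=float(cfg.get("per_peptide_fdr", 0.003)),
        )


def run_evaluation(cfg: RunConfig) -> dict:
    """Execute map -> support/coverage -> consensus -> conflicts ->
    classify -> rescore -> tally and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: genome %s", cfg.genome_path)
    replicons = read_fasta(cfg.genome_path)
    index = FrameIndex(replicons)

    call_sets: dict[str, GeneCallSet] = {}
    for cid, path in cfg.caller_gffs.items():
        call_sets[cid] = read_gene_calls(path, cid)
        logger.info("stage read: caller %s, %d calls", cid, len(call_sets[cid]))

    peptides = []
    for p in cfg.peptide_paths:
        peptides.extend(read_peptides(p))
    logger.info("stage map: %d input peptides", len(peptides))

    mapped, report = map_all(peptides, index)
    logger.info(
        "stage map: %d mapped, %d ambiguous discarded, %d unmatched",
        report.n_mapped, report.n_ambiguous_discarded, report.n_unmatched,
    )
    write_mapping_tsv(mapped, report, out / "mapping.tsv")

    summary: dict = {
        "n_replicons": len(replicons),
        "mapping": {
            "n_input": report.n_input,
            "n_mapped": report.n_mapped,
            "n_ambiguous_discarded": report.n_ambiguous_discarded,
            "n_unmatched": report.n_unmatched,
            "n_short_flagged": report.n_short_flagged,
        },
        "min_support": cfg.min_support,
        "per_peptide_fdr": cfg.per_peptide_fdr,
        "joint_false_rate": joint_false_rate(cfg.per_peptide_fdr,
                                             cfg.min_support),
        "callers": {},
    }

    all_errors = []
    support_rows = []
    for cid, calls in call_sets.items():
        sup = peptide_support(mapped, calls, index)
        conflicts = find_conflicts(mapped, calls, index)
        assert sup.n_conflicting_peptides == len(conflicts), (
            "support/conflict partition violated"
        )
        write_conflict_gff(conflicts, out / f"conflicts_{cid}.gff3")
        errors = classify_errors(conflicts, calls, index,
                                 min_support=cfg.min_support)
        errors = rescore_pseudogenes(errors, calls, mapped, index,
                                     min_support=cfg.min_support)
        all_errors.extend(errors)
        by_cat = {
            cat: sum(1 for e in errors if e.category == cat)
            for cat in ("wrong", "short", "missed")
        }
        logger.info("stage classify: caller %s -> %s", cid, by_cat)
        summary["callers"][cid] = {
            "n_calls": len(calls),
            "n_supporting_peptides": sup.n_supporting_peptides,
            "n_conflicting_peptides": sup.n_conflicting_peptides,
            "n_genes_with_peptide": sup.n_genes_with_peptide,
            "coverage_percent": round(sup.coverage_percent, 4),
            "errors": by_cat,
        }
        support_rows.append(
            {
                "caller": cid,
                "n_supporting_peptides": sup.n_supporting_peptides,
                "n_conflicting_peptides": sup.n_conflicting_peptides,
                "n_genes_with_peptide": sup.n_genes_with_peptide,
                "n_genes_total": sup.n_genes_total,
                "coverage_percent": round(sup.coverage_percent, 4),
            }
        )

    pd.DataFrame(support_rows).to_csv(out / "support.tsv", sep="\t", index=False)
    errors_to_frame(all_errors).to_csv(out / "errors.tsv", sep="\t", index=False)
    tally_errors(all_errors, ("caller", "replicon", "category")).to_csv(
        out / "error_tally.tsv", sep="\t", index=False
    )

    if len(call_sets) >= 2:
        cons = consensus_summary(list(call_sets.values()))
        summary["consensus"] = cons.to_dict()

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary


def bias_report(
    replicons: Sequence[Replicon],
    peptide_counts: dict[str, int],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-replicon GC / length / peptide-count table with rank
    correlations of length-vs-GC and peptides-vs-GC.

    Spearman's rho is used (average ranks for ties); a constant column
    has no ordering signal and is reported as correlation 0.
    """
    if len(replicons) < 2:
        raise ValueError("need at least two replicons")
    df = pd.DataFrame(
        {
            "replicon": [r.id for r in replicons],
            "gc_percent": [r.gc_percent for r in replicons],
            "length_mbp": [r.length / 1e6 for r in replicons],
            "n_peptides": [peptide_counts.get(r.id, 0) for r in replicons],
        }
    )

    def rho(x, y) -> float:
        if len(set(x)) < 2 or len(set(y)) < 2:
            return 0.0
        return float(stats.spearmanr(x, y).statistic)

    corr = {
        "spearman_length_vs_gc": rho(df["length_mbp"], df["gc_percent"]),
        "spearman_peptides_vs_gc": rho(df["n_peptides"], df["gc_percent"]),
    }
    return df, corr
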