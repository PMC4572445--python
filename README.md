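# progeval

Proteogenomic evaluation of prokaryotic structural genome annotation.

Shotgun-proteomics peptides are direct evidence of translation: a peptide
that maps onto the genome *outside* the boundaries of every predicted gene
contradicts the annotation. `progeval` turns that idea into a reusable,
tested pipeline for anyone comparing ab initio gene callers (GeneMarkS,
Glimmer3, Prodigal, post-processors such as GenePRIMP) or auditing an
annotation against peptide evidence:

1. **Peptide mapping** — each identified peptide sequence is searched for an
   exact, unique match in one of the six translation frames of the genome;
   ambiguous peptides (>1 locus) are discarded, and the mapped/ambiguous/
   unmatched counts always partition the input.
2. **Support and coverage** — a peptide *supports* a gene call when it lies
   wholly inside the call on the same strand and reading frame; per-caller
   coverage is the percentage of genes with at least one supporting peptide.
3. **Caller consensus** — identical calls (same replicon, strand, start,
   stop), stop-only agreement (start codon free), unique calls, and the
   dual-denominator percentages for 2..k callers.
4. **Conflict classification** — peptides conflicting with a call set are
   scored with the three detectable error categories:
   * **wrong** — ≥ 2 non-redundant peptides overlap a call in a different
     reading frame;
   * **short** — ≥ 2 non-redundant in-frame peptides start 5′ of the
     annotated start, inside the call's maximal in-frame ORF extension;
   * **missed** — ≥ 2 non-redundant peptides share strand and frame in one
     maximal ORF overlapping no call.
   Pseudogene-tagged calls whose retained CDS fragments contain confirming
   peptides are re-scored as **missed** real genes; untagged frameshifted
   calls with confirming peptides are good calls.  Requiring two
   non-redundant peptides at a per-peptide FDR *q* gives a joint
   false-positive probability of *q*² (9 × 10⁻⁶ at *q* = 0.003).
5. **Synthetic data** — a generator produces replicons of chosen GC% and
   length, a truth gene set, caller-style perturbed call sets (start
   truncations, deletions, wrong-frame replacements, pseudogene-tagged
   frameshift splits) and tryptic peptide evidence, with a complete
   planted-error ledger so every stage can be validated exactly.

## Worked example

Simulate a 50 kb replicon with 35 genes and two imperfect "callers"
(3 short + 2 missed + 2 wrong errors planted for `genemark`; 1 short,
1 missed and 1 mistagged pseudogene for `prodigal`), then evaluate:

```bash
progeval simulate --config sim.yaml --seed 17 --out-dir bundle
# wrote benchmark to bundle: 35 genes, 638 peptides, 10 planted errors
progeval run-all --config run.yaml
# {"n_ambiguous_discarded": 0, "n_input": 638, "n_mapped": 638, ...}
```

`run_out/summary.json` then contains (abridged):

```json
"genemark": {
  "n_calls": 33,
  "n_supporting_peptides": 565,
  "n_conflicting_peptides": 73,
  "coverage_percent": 93.9394,
  "errors": {"missed": 2, "short": 3, "wrong": 2}
},
"prodigal": {
  "n_calls": 34,
  "n_supporting_peptides": 614,
  "coverage_percent": 100.0,
  "errors": {"missed": 2, "short": 1, "wrong": 0}
}
```

Every planted error is recovered: the three categories for `genemark`
match the plan, and `prodigal`'s two missed genes are its one deleted gene
plus the mistagged pseudogene re-scored from its confirming peptides.
Alongside the JSON the run directory holds `mapping.tsv` (per-peptide
status), `support.tsv`, `errors.tsv`, `error_tally.tsv`, and a GFF3
conflict track per caller for genome-browser inspection.

Each stage is also independently invocable (`progeval map`, `compare`,
`classify`, `report`) or callable as a library
(`progeval.map_all`, `classify_errors`, `consensus_summary`, ...).

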