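# Methods

## Coordinates, frames, and translation

All internal coordinates are 0-based half-open `[start, end)` on the
forward genomic axis; 1-based inclusive coordinates appear only in GFF3
files.  Reading-frame labels are intrinsic to the strand-oriented
reading: on `+` the frame of a codon starting at `s` is `s mod 3`; on `-`
the frame of a codon ending at genomic `e` is `(L − e) mod 3` for a
replicon of length `L`.  Under this convention a frame label equals the
translation offset on the strand-oriented sequence for both strands, so
"same frame" is a single integer comparison between any peptide and any
gene call.  Translation uses genetic code table 11 (the prokaryotic
standard), with ATG/GTG/TTG accepted as alternative starts when flagging
ORFs that contain a start codon.  Codons containing `N` translate to `X`
unconditionally — even when the ambiguity would resolve (e.g. GGN → Gly)
— because peptide matching must never succeed across unknown sequence.

A *maximal ORF* is a stop-to-stop stretch in one frame with no internal
in-frame stop, bounded by in-frame stops or the sequence edge; the
bounding stop codons are excluded from its interval.  The default
minimum ORF length is 39 nt, the shortest experimentally confirmed CDS;
the ab initio callers' own defaults (81–120 nt) can be passed instead.

## Peptide mapping

A peptide maps when its sequence occurs exactly once across all six
frames of all replicons.  Uniqueness is genome-wide (all replicons, both
strands): "unique" is ill-defined per replicon for multi-replicon
organisms.  I and L are distinct residues during matching — stricter
matching can only discard more peptides, never invent a match.  Peptides
shorter than 6 aa are flagged as high ambiguity risk but processed;
only peptides that actually hit more than one locus are discarded.
Peptides arriving with pre-mapped coordinates are validated by
re-translating the claimed interval and accepted without search;
validation failures are logged and counted as unmatched.  The search
scans the six frame translations directly with C-level substring search,
stopping at the second occurrence; its contract (exactness, uniqueness
counting) is checked against a position-by-position enumeration oracle
in the test suite.

## Support, conflicts, and error categories

A peptide *supports* a call when it lies wholly inside the call's
interval, on the call's strand, in the frame of a CDS fragment it
overlaps.  Frame agreement, not mere containment, is required: a
wholly-contained wrong-frame peptide must be able to expose a wrong
call.  For every caller, supporting + conflicting = mapped, an invariant
asserted at run time.

Non-supporting peptides are labelled by geometry: `overlaps_out_of_frame`,
`extends_upstream` (in frame with an overlapped call but starting 5′ of
its start), `spans_boundary` (in frame, past the 3′ end), or
`outside_all`.  One deliberate extension: a peptide that overlaps no call
but sits in-frame within the maximal-ORF *upstream extension* of a call
is classed `extends_upstream`, not `outside_all`.  Upstream peptides
contradict that call's start whether or not they touch it, and the
alternative would fabricate a "missed gene" inside an already-called ORF.

Classification (each error needs ≥ `min_support` = 2 peptides at
*distinct genomic intervals*; re-observations of one locus count once,
overlapping distinct tryptic peptides count separately):

* **wrong** — peptides overlapping one call, all sharing a frame
  different from the call's, grouped per maximal ORF of the peptide
  frame; the implied interval is that ORF.
* **short** — upstream in-frame peptides, each inside the call's maximal
  in-frame ORF extension (a peptide 5′ of an in-frame stop cannot belong
  to the same protein); the implied interval extends the call to the
  most 5′ supporting peptide.
* **missed** — `outside_all` peptides sharing strand and frame within one
  maximal ORF; the implied gene is the stop-to-stop ORF, flagged as
  implied because the true start is unknowable from peptides.
* `spans_boundary` conflicts are recorded but feed no category: there is
  no detectable error class for 3′ extension.

Relations feed disjoint categories, so no peptide contributes to two
errors of different categories against the same caller.

Pseudogene re-scoring operates on the mapped peptides directly (its
confirming peptides are supporting peptides, so they never double-count
in conflict-derived errors): a pseudogene-tagged call whose fragments
contain ≥ 2 confirming peptides yields a missed error at the call's
locus; an untagged multi-fragment (frameshifted) call with confirming
peptides yields nothing — the absence of the tag was correct.

The two-peptide rule's joint false-positive probability is computed by
the product rule `q^k` for `k` independent peptides at per-peptide FDR
`q`: 0.003² = 9 × 10⁻⁶.  Published figures sometimes quote looser bounds
(e.g. 0.09 %); the product rule is reported exactly and such figures are
treated as upper bounds.

Detecting "too long" start calls and false-positive gene calls is out of
scope by construction: peptides can confirm coding sequence but never
deny it, and no peptide can appear upstream of a start that is already
upstream of the truth.

## Consensus statistics

Two calls are identical when replicon, strand, start and end all agree;
they stop-agree when they share the 3′-terminal coordinate on the coding
strand (end for `+`, start for `-`) but differ in start.  "Stop" must be
strand-aware or minus-strand genes would compare start against stop.
The summary reports each overlap count under every caller's own
denominator (the same numerator divided by each caller's total), plus
unique calls (identical in no other set) and the all-way sets; the
all-way identical set is a subset of every pairwise identical set by
construction.  Whether a producer's intervals include the stop codon is
a dialect question; inputs are compared as read, and mixed-dialect
inputs should be normalized before comparison.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, not
any particular organism:

* **Replicons** — genes placed non-overlapping on both strands, each
  ATG-initiated with its single in-frame stop at the 3′ end, separated by
  random intergenic spacers, padded to the requested length.  Coding
  codons are sampled from the 61 sense codons weighted by per-base
  probabilities at the GC target (codon-bias sampling keeps ORFs
  stop-free while matching composition; realized GC lands within ±2
  points at 100 kb).  Defaults: 100 kb, 80 genes, GC 57.7 % (the average
  of the published genome panel; valid range 30–74 %), gene length
  ~N(900, 200) nt with a 300 nt floor, intergenic ~N(150, 80) nt with a
  30 nt floor.
* **Caller perturbations** — per gene: start truncation (in-frame,
  ≥ 9 nt, planted "short"), deletion ("missed"), replacement by a
  frame-shifted call over the same locus ("wrong"), or a frameshift
  split into CDS fragments separated by a 3 nt in-frame gap, tagged as a
  pseudogene ("missed" after re-scoring) or untagged (no error).
  Profiles take per-gene probabilities or exact counts; every planted
  deviation is written to a ledger with its expected category.  Planted
  errors require at least three detectable tryptic peptides on the
  relevant side (e.g. upstream of a truncation) so that the two-peptide
  evidence rule survives the occasional ambiguity discard of a short
  peptide.
* **Peptide evidence** — each gene is expressed with probability 0.4
  (the sub-half expression rate proteogenomic surveys observe); expressed
  proteins are digested with the expasy trypsin rule (cleave after K/R,
  not before P), length-filtered to 6–50 aa, and each peptide is detected
  with a configurable probability.  False identifications are emulated at
  rate 0.003 per emitted peptide by decoys drawn from wrong-frame or
  non-coding six-frame substrings, rejection-sampled to map uniquely so
  they exercise the false-discovery pathway rather than the ambiguity
  discard.

What the generator does **not** model: ribosome-binding sites, promoter
or codon-usage realism beyond GC, signal-peptide cleavage, hydrophobic
peptide detectability, spectrum-level noise, and the instrument- and
study-design biases that couple peptide counts to GC content in real
compilations.  Passing tests therefore demonstrate correctness of the
scoring machinery under the stated statistical conditions, not
performance claims about any real genome.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of the
analysis: 100 kb / 80-gene benchmarks for planted-error recovery
(10 short + 10 missed + 10 wrong + 3 mistagged pseudogenes, noiseless
detection), twenty 10–50 kb replicons for mapping-oracle agreement, and
200–250-gene simulations for consensus and coverage calibration, checked
against closed forms within 3σ binomial bounds (99 % interval for
coverage).  Determinism: all randomness flows from one integer seed per
operation; benchmark bundles are byte-identical per seed, and evaluation
reruns produce byte-identical JSON (no timestamps).  Ties in the bias
report's rank correlations use average ranks; a constant column is
reported as correlation 0.  Degenerate inputs (empty peptide file, empty
call set, header-only GFF3) are data states, not errors.

## Known limitations

* Multi-fragment calls use each fragment's own frame; peptides spanning
  a fragment boundary are credited when they overlap any in-frame
  fragment, which is permissive for 3 nt in-frame gaps.
* `wrong` errors attribute peptides to the overlapped call with the
  largest overlap; pathological nested call arrangements could split
  evidence between calls.
* BLASTp / conserved-domain verification of error calls is intentionally
  not performed; the classifier's output is peptide evidence only.
* The GFF3 reader targets standard GFF3 with `Parent`/`ID`/`locus_tag`
  grouping and both `pseudogene`-type and `pseudo=true` dialects;
  exotic producer dialects may need pre-normalization.
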