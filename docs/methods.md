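# Methods

## Coordinate and format conventions

All internal coordinates are 0-based half-open, so `length = end - start`
everywhere and interval arithmetic never needs ±1 corrections.  GFF3
(1-based inclusive), BLAST tabular (1-based inclusive, possibly reversed
on the minus strand) and AGP (1-based inclusive) are converted exactly once,
at the reader/writer boundary; every reader/writer pair is a typed
round-trip identity on valid input, which the test suite enforces.  Only
gene-level GFF3 rows (`gene`, `pseudogene`) are consumed: the downstream
procedures operate on gene models, not transcripts or exons.

## Anchoring

The anchoring vote needs one chromosome per gene.  `best_hits` ranks a
gene's hits by bitscore, then alignment length, then lexicographically
smallest subject, then subject start — a total order, so output is
independent of hit-table row order (property-tested).  Bitscore is the
conventional best-hit criterion; percent identity is parsed but unused by
default.  Multiple HSPs between one gene and one chromosome are *not*
summed by default — the best single HSP represents the pair — because
summation rewards fragmented spurious alignments; `sum_hsps=True` enables
the summed variant for users who want it.  A tie in top bitscore across
distinct chromosomes is reported (`ambiguous=True`) rather than resolved
silently.

Classification uses the strict rule: conserved iff the top chromosome holds
*more than* half the votes, so an exact 50/50 split is rearranged.  The
denominator is the genes *with* assignments by default (`hit_genes`):
genes without any hit carry no information about which chromosome a
scaffold came from, only about annotation/alignment sensitivity.  The
`all_genes` denominator is exposed for users who prefer the conservative
reading.  The length cutoff defaults to 1 Mb (anchor only scaffolds large
enough to carry a meaningful vote); the simulator's scaffolds are
intentionally smaller, so simulated analyses pass `min_len_bp=0`.

Percent shares in the summary are computed over classified
(conserved + rearranged) bp, rounded to integers by the largest-remainder
method so they always sum to 100; unplaced bp is reported but never
dilutes the two-way split.

## Hypothetical chromosomes

The anchoring literature rarely specifies intra-chromosome ordering; the
rules here are a deliberate, deterministic extension.  Position = median
subject midpoint of the genes voting for the assigned chromosome (median
rather than mean: robust to a minority of translocated genes).  Orientation
= sign of the Kendall rank correlation between gene order along the
scaffold and subject position; zero correlation or fewer than two
informative (untied) pairs defaults to `+` with `low_confidence=True`.
Ties in median position break by longer scaffold, then name.  AGP output
uses 100 bp `U` gaps of type `scaffold` (linkage `no`), a conventional
placeholder with no biological meaning, and object IDs `hypChr<N>`.

## Syntenic loss detection

"Absent ortholog" means absent from the orthology map (query gene →
reference gene, built by locating each best hit's subject midpoint inside
the reference gene models).  The detector scans up to `max_flank_scan`
(default 3) reference genes on each side of an ortholog-less gene for the
nearest flanks *with* orthologs.  Both flank orthologs on one scaffold with
at most `max_intervening` (default 0, strict adjacency) unrelated query
genes between them ⇒ `syntenic_loss`, and the interval between the flank
orthologs' inner edges is reported in query coordinates, symmetric under
scaffold orientation.  Flanks on different scaffolds ⇒
`unresolved_split_flanks`; no flank in range ⇒ `unresolved_flank_missing`;
too many unrelated intervening genes ⇒ `unresolved_intervening_genes`.
"Unrelated" means: not an ortholog of a reference gene lying between the
two flanks, so a run of k consecutive lost genes yields k calls sharing one
interval.  Residual-similarity scanning of the interval (e.g. translated
BLAST) is deliberately out of scope — the interval coordinates are the
hand-off for that external check.  A gene whose hit was simply missed is
indistinguishable from a lost gene *by this evidence alone*; that is a
property of the method, not the implementation, and the noisy-simulation
tests characterise exactly this failure mode.

## Dollo census

The root is fixed all-present — appropriate for post-duplication gene
complements where the ancestor demonstrably had the full set — and gains
are never inferred.  Under that assumption the minimum-loss placement is
unique: the edges above the maximal subtrees whose leaves all lack the
gene; a gene absent everywhere is lost once on the root's stem branch
(named after the root node, `root` by default).  The exhaustive-search
oracle in the tests confirms minimality and uniqueness on all matrices up
to 5 genes × 4 taxa across three topologies.

`pseudogene_mode` exists because published gene tallies are internally
mixed about pseudogenes: `as_absent` (default) treats a pseudogene as lost
function and assigns its loss with the absences, which reproduces
ancestor-level loss lists that pool pseudogenes with deletions;
`as_present` counts the locus as retained, moving such genes to
terminal-branch losses.  The packaged Hox fixture (19 genes, striped
catfish vs zebrafish) encodes the three zebrafish HoxA pseudogenes as Ψ so
both readings are computable; under `as_absent` it yields 8 stem, 3
catfish, 5 zebrafish losses and an intact-count difference of
catfish − zebrafish = 2 on the loss-list genes.

## The simulator

The generator emulates the study design the pipeline targets: a reference
genome of 29 chromosomes × 200 gene models (2 kb genes, 8 kb intergenic
spacers — genome-like gene density at a desk-scale total of 5800 genes), a
derived genome shaped by, in order, reciprocal block translocations
(contiguous 10-gene blocks exchanged between chromosomes — rearrangement
at the granularity the anchoring procedure sees; finer events such as
inversions are out of scope), one fission by default (n = 29 → n = 30,
matching the karyotype difference the pipeline is meant to explain), gene
losses and pseudogenizations, and finally fragmentation into scaffolds
with geometric gene counts (mean 25, giving ~230 scaffolds and a
realistic size spread).  Fragmentation breakpoints fall only in intergenic
space: the anchoring unit is the whole gene model, so split genes are not
modelled.  Scaffold names follow the `sc0000001` convention of draft fish
assemblies.

Hit noise has three channels: `hit_miss_rate` (a gene has no hit at all —
annotation/alignment dropout), `spurious_hit_rate` (an extra hit on a
random chromosome with bitscore uniform in [50, 300]) and
`paralog_tie_rate` (an equal-bitscore second hit on another chromosome —
an unresolved paralog).  True hits score 500 ± 5 (uniform jitter), so at
zero noise the best hit is always the true origin and parameter recovery
is exact — the clean-data tests assert precisely 100% anchoring accuracy
and loss recall/precision 1.0.  What the simulator does *not* model —
nucleotide-level divergence, repeats, assembly chimerism, gene prediction
errors beyond dropout — bounds what passing tests show about real data:
they validate the inference logic, not robustness to artefacts outside
these noise channels.

All randomness flows from one `numpy` generator seeded by the config;
identical configs produce byte-identical output files, and the pipeline
report contains no timestamps or paths so reproducibility is checkable by
`diff`.

## Problem sizes and numerical choices

Simulation-based tests run the full 29 × 200 design where the property
concerns genome-scale behaviour (clean-data recovery; the
translocation-degradation curve at 0/5/20/50 translocations × 20 seeds
under moderate noise: miss 0.2, spurious 0.2, tie 0.1) and smaller designs
(4–8 chromosomes, 20–60 genes) for oracle-equivalence and unit checks,
chosen so the whole suite completes in seconds.  Ties everywhere break
lexicographically after the stated criteria, so every stage is
deterministic; degenerate inputs (empty hit tables, single-gene scaffolds,
all-absent genes) take explicit, tested branches rather than relying on
library defaults.

## Known limitations

- Best-hit orthology conflates orthologs with best-scoring paralogs; RBH
  flagging mitigates but does not eliminate this.
- Anchoring has no significance measure: a 2-gene scaffold "conserved" at
  2/2 votes and a 200-gene scaffold at 180/200 get the same class.
- Loss detection cannot distinguish gene loss from assembly gaps without
  coverage data, and reports pseudogenes only when the query annotation
  labels them.
- Hypothetical-chromosome ordering ignores within-scaffold breakpoints: a
  chimeric scaffold is placed whole, on its majority chromosome.
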