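# Methods

`periscan` implements a complete desk-scale pipeline for discovering
families of extracellular sensor domains (Cache/PAS-like modules of
prokaryotic signal-transduction receptors) from a proteome, building
calibrated profile models of them, organising the families into
superfamilies (clans), and computing census statistics.  This note
records the models and procedures, their assumptions, the tunable
parameters, and the limits of what the bundled synthetic benchmark can
demonstrate.

## Pipeline overview

```
simulate -> topology -> extract -> reduce -> network -> cluster ->
represent -> align -> build/calibrate -> merge -> scan -> clans -> census
```

Each stage checkpoints into a run manifest with SHA-256 output checksums;
re-running a directory skips stages whose outputs and configuration are
unchanged.

## Membrane topology and region extraction

Topology comes either from an imported TSV (one segment per row, so any
external predictor can be used) or from the built-in hydropathy stand-in:

1. sliding-window Kyte–Doolittle mean (window 19 residues, threshold 1.6 —
   the classic settings);
2. maximal runs of above-threshold window centres become candidate
   membrane segments; runs separated by fewer than 10 below-threshold
   centres are merged (a single noisy window must not split a helix);
3. each candidate's boundaries are refined to the maximal-sum stretch of
   per-residue hydropathy minus 2.0 around the run.  The window average
   blurs helix ends by up to ~6 residues; per-residue refinement recovers
   them.  The centring constant 2.0 means only unambiguously TM-grade
   residues (I/L/V/F/C at KD ≥ 2) extend a helix, which keeps moderately
   hydrophobic (Ala-rich) loop stretches out of the membrane call;
4. loops alternate inside/outside from a configurable N-terminal
   orientation (default "N-in", matching the simulated architectures; the
   stand-in does not model orientation signals — import real predictor
   output when orientation matters).

A candidate sensor region is an *outside* segment strictly between two
membrane segments and **longer than 50 residues** (strict: 50 rejected, 51
kept; configurable).  Regions are kept only if the parent protein has an
output-domain hit *outside* the region's coordinates — the receptor must
have a separate cytoplasmic effector module.

## Similarity network and clustering

All-vs-all optimal Smith–Waterman local alignment (BLOSUM62, affine gaps
11/1, via Biopython's PairwiseAligner) over the redundancy-reduced
regions.  Raw scores become bit scores via the standard ungapped
Karlin–Altschul constants (λ = 0.3176, K = 0.134) and E-values via
`E = m·n·2^(−bits)`.

*Coverage* is the fraction of a sequence's residues in gap-free alignment
columns — not the start-to-end span.  Span-based coverage credits
arbitrarily long internal gaps, so one lucky 3-residue match near a
sequence end can stretch a core-only alignment past any coverage
threshold; residue-based coverage cannot be gamed that way.  *Identity* is
matches over alignment columns for network hits, and matches over the
shorter sequence for redundancy reduction (mirroring the BLAST vs CD-HIT
conventions).

Redundancy reduction is greedy incremental clustering at 90% identity:
longest first, each sequence joins the first retained sequence it matches,
else is retained.  An exact edit-distance bound (edlib) prunes pairs whose
identity cannot reach the threshold before any full alignment is run.

Graph edges require **both** directional hits to pass E < 1e-10 and
coverage > 95% (strict inequalities).  Connected components are the
clusters; those with ≥ 10 members proceed to model building.  Per cluster,
representatives are chosen by the greedy maximum-coverage procedure: each
query represents its qualifying hits (self included); duplicate/subset
represented sets are discarded once up front; then the set growing the
working set most is selected until the cluster is covered.  All tie-breaks
(larger raw set, then lexicographically smaller id) are deterministic and
recorded.

## Profile models

Cluster members are aligned by a progressive aligner (UPGMA guide tree on
3-mer distances; profile–profile merges under expected BLOSUM62 scores
with affine gaps).  Imported alignments can substitute.

The family model is a profile HMM: match states with per-residue emission
distributions, shared background insert emissions, match/insert/delete
transitions.  Construction: columns with ≥ 50% residues are match states;
Henikoff position-based sequence weights; emissions are weighted counts
plus a fixed-mass background pseudocount (weight 1.5, so its influence
decays as observations accumulate); transitions from weighted path counts
with Laplace smoothing (+1).  Insert runs adjacent to deletions are
attributed to the source match state's insert track (the model forbids
I↔D transitions, as is conventional).

Scoring is fully local: uniform entry into any match state (1/L), exit
from any match state (probability 0.05 reserved per internal state, forced
at the last), flanking residues emitted by the background at odds 1, and a
uniform 1/(n+1) prior over start positions.  The **forward score** is the
log2 of the path-summed odds; an empty sequence has no emitting path and
scores −inf by definition.  The forward and Viterbi recurrences are
numba-compiled; the forward kernel is verified against exhaustive path
enumeration to 1e-9 relative on toy models.

### Calibration and E-values

Each model is calibrated on random sequences drawn from a stated
composition (the pipeline passes the composition of the scanned universe).
A Gumbel law is fitted to the forward scores **with the scale fixed at
1/ln 2**: the high tail of a log2-odds forward score decays like 2^(−s),
and a free two-parameter fit — dominated by the bulk of the null — decays
faster than the true tail, underestimating P-values by orders of magnitude
exactly where detection thresholds live.  `E = n_targets · P(S > s)`.
The free two-parameter fit remains available (and is what the
profile–profile shuffle calibration uses, since alignment maxima are
genuinely Gumbel).

### Scanning

Per protein and model: the full-sequence forward score gives the sequence
E-value; domain envelopes come from iterative Viterbi segmentation (best
path span, then recursion into the flanks), each envelope re-scored by
forward on its own span for the domain E-value.  Detection requires both
E-values ≤ 1e-3.  Overlapping hits from related models are all reported;
census statistics use clan-style competition (best model per region, ties
by lower E then model id).

## Profile–profile comparison and clans

Column-pair score `log2 Σ_x p_a(x)·p_b(x)/q(x)`; Smith–Waterman over match
columns with affine gaps (open 7, extend 1 bits — gaps are expensive
because genuinely homologous profile pairs align collinearly, while
shuffled-column nulls need many offset jumps).  Significance by column
shuffling: 100 re-alignments against column-permuted copies of the second
model, Gumbel-fitted; `E = n_comparisons · P`.

The **probability score** is defined operationally as `100·(1 − P)`.
All 0–100-scale thresholds in the package (dotted tier > 90, heat-map
floor 20, merge bar 90) refer to this statistic.  It saturates near 100
for any significant relationship, which is why the cluster-merging step
carries a second criterion: clusters merge only when reciprocally linked
above the probability bar **and** aligned-column coverage ≥ 0.6 **and**
alignment strength ≥ 2 bits per aligned column.  Same-family fragments
share near-identical column distributions (~2.5–3 bits/column); distinct
families of one superfamily are significant but weak per column (≤ ~1.7).
Merging iterates to an order-independent fixed point.

The family network has three reciprocal tiers: thick (E < 1e-3), thin
(E < 1e-1), dotted (probability > 90) — the E-value tiers are the
conventional clan-membership thresholds, the probability tier catches
remoter links.  Clan assignment is a three-rule cascade iterated to a
fixed point: (1) thick reciprocal edge to a clan member; (2) unique
closest clan by best probability; (3) mutual best hit with an assigned
model.  Conflicting rule-1 evidence flags the family ambiguous rather than
forcing a choice.

Family similarity is summarised two ways: a UPGMA dendrogram on
`distance = 100 − probability` (asymmetric scores symmetrised by the
arithmetic mean; scipy average linkage, branch heights = merge distance/2,
Newick export) and a Ward-clustered heat map of the probability matrix
floored at 20.  Tandem (double) domains can be split at a supplied match
column into membrane-distal (N) and membrane-proximal (C) sub-profiles
and compared against the single-domain models.

## Census

Per-family domain-length summaries with outliers outside configurable
bands centred at the reference lengths 140 (single) and 271 (double)
residues, ±35% by default; region coverage = clamped domain length over
region length, binned at 10 percentage points with 100% closed into the
top bin (percentages sum to 100 by construction); abundance ranking with
one best-scoring model per region; and the phyletic matrix — presence if
*any* strain of a species has a hit, species under the protein-count floor
(default 1000; scaled to 20 for the synthetic benchmark) dropped, clade
roll-up by any-descendant presence.

## The synthetic benchmark

The generator emulates the input universe of a real census — membrane
receptors with the layout N-tail(in)–TM–sensor(out)–TM–linker(in)–output
domain — plus intracellular decoys (a family domain placed
cytoplasmically) and sensorless decoys (a random extracellular loop), with
a full ground-truth table.  Defaults: 300 proteins, 6 families × 40
members at 0.25 substitutions/site from the family consensus, TM length
21, two superfamilies.

Design choices that matter:

* **Soluble composition.**  Loops and domains are drawn from a
  hydrophobic-depleted background, and consensi are rejected while any
  19-residue window reaches TM-grade hydropathy or any ≥3-residue strong
  hydrophobic run exists.  Real extracellular soluble domains are depleted
  in strong hydrophobics for the same physical reason; domains that looked
  like membrane helices would be misannotated by any hydropathy method and
  are excluded from the simulated universe by construction.
* **Superfamily = conserved core + family periphery.**  Families of one
  superfamily share a core ancestor (60% of the domain length) of which
  55% of positions are conserved anchor motifs; non-anchor core positions
  substitute at 0.7/site, and each family adds fresh random flanks of
  family-specific length.  This mirrors how real clans cohere through
  conserved structural cores: cross-family similarity is confined to the
  core (so members of different families can never align at > 95%
  reciprocal coverage and fuse sequence clusters), while profile-level
  comparison of the cores is decisive (reciprocal E ≪ 1e-3).
* **Determinism.**  All randomness flows from one integer seed; per-task
  substreams are spawned from it, so generation is reproducible and
  order-independent.

What the generator does **not** model: real phylogenetic correlation
(members are i.i.d. around a consensus), codon-level evolution, signal
peptides, TM helix grammar beyond composition, compositional drift across
taxa, or the domain-length/architecture diversity of real receptor
families.  Passing the benchmark therefore demonstrates the pipeline's
internal correctness and calibration — not detection performance on real
databases, where divergence structure is harsher and topology prediction
errors are correlated with sequence features.

## Problem sizes and numerical choices

The default study conditions (≈300 proteins, 6 × 40 members, divergence
0.25) complete the full pipeline in about one minute on one CPU and are
what the test suite and `scripts/acceptance.py` exercise.  Calibration
uses 300 random sequences of length 200 per model; profile–profile nulls
use 100 column shuffles.  Forward DP uses per-row rescaling (triggered
beyond 2^±500) rather than log-space, keeping the enumeration-oracle
agreement at 1e-9 relative while staying fast.  Ties everywhere
(representative selection, redundancy order, UPGMA joins, abundance
credit) break deterministically by size then lexicographic id.

## Known limitations

* The hydropathy stand-in has no orientation model; "N-in" is an
  assumption, not a prediction.  Import real predictor output for real
  data.
* The operational probability score is not HHsearch's posterior; its
  absolute scale is comparable only within this package.
* Domain envelopes come from Viterbi spans, not posterior envelope
  inference; boundary uncertainty is a few residues even on clean data.
* The E-value model assumes i.i.d. background targets; compositionally
  biased real sequences would need a null-correction the package does not
  implement.
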