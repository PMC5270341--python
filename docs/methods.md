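# Methods

This note documents the models, parameter choices, and numerical rules
behind chromoscope, and what its simulation-based validation does and
does not demonstrate.

## Breakend model and derivative reconstruction

A junction joins two breakends; a breakend is `(chrom, pos, side)` with
`pos` a 0-based cut coordinate between bases and `side` the retained
flank (`left` keeps `[.., pos)`, `right` keeps `[pos, ..)`). In BEDPE
input the strand column carries the side (`+` = left flank) and the
breakend coordinate is the interval end for both strands; the package's
own BEDPE writer uses the same convention, so junction files round-trip
exactly. This encoding is documented with diagrams in
`rearrangements.py` because breakend conventions vary between tools and
are the commonest source of orientation bugs.

Reconstruction is a path decomposition of the breakpoint graph: nodes are
segment extremities (segments come from cutting each chromosome at every
breakend position), edges are reference adjacencies whose shared position
no junction uses, plus the junction adjacencies. Maximal
telomere-to-telomere paths are the derivatives; everything else is
deleted material, with reference-adjacent lost segments merged into
maximal deleted fragments. Consequences of this model:

* **Copy-number neutrality.** Each segment appears at most once. An
  extremity claimed by two adjacencies (a duplication junction) raises
  `ConflictingJunctionsError` rather than being silently resolved; a
  closed path with no telomere raises `CircularDerivativeError`.
  Both are explicit non-goals of the model, matching the event class it
  targets (inversions, translocations, deletions).
* **Determinism.** Whole-derivative orientation is normalized so the
  first part's (chromosome, start) is minimal, derivatives are sorted by
  that key and named `der<i>_<chrom of first telomere>`; the dominant
  chromosome by content is kept as metadata. Identical inputs give
  byte-identical outputs.
* **Mass conservation** (derivatives + deleted = reference) is asserted
  on every assembly.

Liftover uses per-derivative block tables (cumulative part lengths;
reverse blocks map `der_offset i -> ref_end - 1 - i`) with vectorised
`searchsorted` lookups. Deleted reference positions return an explicit
deleted marker, not an error, because callers legitimately probe them
(e.g. placing gene fragments).

Junction microhomology and untemplated insertions are ignored: junctions
are treated as blunt, so derivative lengths are exact sums of segment
lengths.

## Gene-effect classification

Precedence is deleted > truncated > proximal > distal, each gene
receiving exactly one category. "Within 1 Mb" is operationalized as gap
distance (0 if touching) from the gene body to the nearest breakend,
window default 1,000,000 bp and configurable; the proximal set is
non-decreasing in the window. A breakend exactly at a gene or TAD edge
counts as outside (strict interior rule) — half-open coordinates make
this unambiguous. Genes straddling a deleted-fragment edge contain that
edge's cut strictly, so they classify as truncated with the removed
fragment marked deleted, which matches fragment-wise expression
accounting.

Fusion configuration is decided by orientation algebra. Locally orient
the derivative around a junction as `[flank_a][flank_b]`; a gene on
flank a transcribes in derivative-forward direction iff
`(side_a == left) == (strand == '+')`, on flank b iff
`(side_b == right) == (strand == '+')`. Equal directions give a
collinear `same_strand` candidate (one gene's promoter-bearing 5'
fragment reads into the other's 3' fragment); unequal directions give an
`opposite_strand` read-through candidate. The test suite checks all 16
side/strand combinations against an independent oracle that walks the
assembled derivative through the coordinate map.

TAD boundaries, when not supplied, are derived as inter-TAD gaps widened
by a symmetric 40-kb flank (the bin scale of the domain calls this
package expects as input). Whether deletion overlap alone counts as TAD
disruption is exposed as a flag (`count_deletion_overlap`, default off:
only breakend containment counts).

## Trio expression analysis

Size factors are the median-of-ratios estimator: for sample j,
`s_j = median over features i with positive geometric mean of
c_ij / geomean_i`. Two derivations worth recording: (1) because the
geometric-mean reference includes every sample, scaling one sample by c
moves its factor by `c^(1-1/m)` and every factor ratio by exactly c,
leaving relative normalized expression invariant up to the global
constant `c^(1/m)`; (2) renormalizing an already-normalized matrix gives
factors all equal to the old factors' geometric mean — exactly 1 on
separable fixtures (counts = feature baseline x sample scale). An
independent implementation (pydeseq2) is used as a cross-check oracle in
the tests.

Comparison rules, all configurable with these defaults:

* expression floor 10 normalized counts, strict (`> 10`), applied per
  compared side; a feature with both sides at or below the floor is
  `not_expressed`, excluded from effect calls, and blanked in reports;
* effect threshold: twofold (`|log2 FC| >= 1`) between the patient mean
  and the arithmetic mean of the two parents' means (each individual
  averaged over replicates first, technical replicates folded into their
  line). Per-parent fold changes are emitted alongside so a stricter
  vs-each-parent rule can be applied downstream;
* pseudocount 1 normalized count in fold changes, preventing division by
  zero below the expression floor;
* no multiple-testing machinery: the effect definition is a fold-change
  gate, not a p-value.

NPC day-7 and day-10 samples of a line are merged (mean of normalized
counts) before comparison; the merge rule is a declarative function.
Hierarchical clustering for the merge rationale uses the 500
highest-variance features of `log2(normalized + 1)` (ties broken by
feature id), complete linkage on Euclidean distances.

Fragment-level expression sums member-exon counts per fragment of a
truncated gene; an exon split by a breakend contributes pro-rata by
overlap length. Fragment counts share the full matrix's size factors.

## Contact analysis

Viewpoint profiles are normalized so captured reads outside a +/-10 kb
exclusion zone around the viewpoint sum to 1e6. The exclusion zone keeps
self-ligation signal from dominating the total; the conventional 500-read
ceiling is applied in display tracks only, never in calls.

The enhancer caller sums overlapping normalized bins (partial bins
pro-rated) and forms the pseudocounted ratio `(patient + 5)/(control +
5)`. Allelic mixture: capture data cannot separate the patient's
unaffected and rearranged homologues, so observed signal is a mixture
with fraction m (default 0.5) from the rearranged allele; a t-fold
change there moves the expected ratio only to `(1-m) + m t`. The gain
threshold is therefore `G = 1 + m(t-1)` (1.5 at defaults) and the loss
threshold its reciprocal `1/G` (2/3), chosen as the reciprocal — rather
than the mirror-image mixture bound `(1-m) + m/t` = 0.75 — so that
swapping patient and control maps gain to loss exactly; `1/G` still sits
above the full-loss expectation of 0.5. Calls with both signals below a
50-normalized-read floor are `low_signal`. A practical consequence of
the mixture: even complete relocation of an enhancer changes the
expected ratio only twofold, which is why call margins are evaluated on
relocations whose derivative-distance change is large (cross-derivative
moves), as in the emulated event.

Matrix projection maps each derivative bin to the reference bin holding
its source midpoint. Exact mass conservation (minus deleted bins) holds
when breakpoints align to the bin grid — the regime in which rearranged
maps are interpreted, and how the simulator places contact-scale
breakpoints; sub-bin breakpoints shift at most one bin of mass per
junction. The power-law decay null (`contact ~ distance^-alpha`, alpha
default 1) is the simulator's generative mean and is available as a null
reference profile for callers and plots.

## The synthetic-data generator

The generator emulates the study design end to end; its defaults are the
study conditions.

* **Random events** for the reconstruction screens: up to 12 cuts over 3
  chromosomes (12, 9, 10 Mb), each internal fragment deleted with
  probability 0.25, survivors shuffled and oriented uniformly. Cut
  positions religated in reference configuration are removed from the
  planted truth (they leave no junction), so the emitted junctions
  reconstruct to the truth exactly — the simulator's merging logic is
  independent of the assembler's graph code.
* **The `fig1_like` preset** is a hand-designed deterministic topology
  (coordinates are synthetic; the emulated patient's real breakpoints are
  not published): 17 junctions over chr1/chr3/chr7/chr12 scaled to
  14/12/14/8 Mb, 4 derivatives, 4 deleted fragments; 67 genes within the
  1-Mb window (10 on three deleted fragments, 6 truncated — including an
  opposite-strand gene-gene junction and a collinear one — 51 proximal),
  60 of the 67 expressed; 13 TADs containing breakends and 5 boundary
  intervals inside deletions; an enhancer panel around a viewpoint on an
  inverted fragment with three planted losses, two gains, and one
  unchanged control. Chromosome sizes are desk-scale but all length
  thresholds keep real values, so gene placement respects the window.
* **Counts.** Negative binomial with variance `mu + alpha mu^2`,
  alpha = 0.05 per exon unit (typical bulk RNA-seq); exon draws are
  independent and genes are their exon sums, so a k-exon gene has
  effective gene-level dispersion alpha/k — the generator models
  exon-level counting noise, not shared per-gene biological factors (see
  limitations). Baselines: planted genes have fixed baselines (median
  ~200–1200); bystanders draw log-normal(log 200, 0.6) floored at 100 so
  the planted expressed/not-expressed labels (60 of 67) are unambiguous
  at any sampling seed; "not expressed" genes sit at 0.3 counts.
  Library factors are log-normal (sd 0.15). The sample layout mirrors
  the emulated trio: one blood sample per individual; patient 2 iPSC
  lines, father 2 (one with a technical replicate sharing its line's
  biological mean), mother 1; each line sampled at days 0 (iPSC), 7 and
  10 (NPC). Planted effects: 4 of 8 expressed deleted genes at 0.5
  dosage, the rest compensated (half of deleted genes responding, as
  observed at the RNA level); truncated-gene fragments with independent
  multipliers (the `FOXP1L`-like gene: 5' x1.6, 3' x0.5 — the planted
  50% loss emulating the reported ~55% reduction); one positional gene
  (`TWIST1L`-like) at 4x in NPC only and silent in blood for every
  individual. The 4x magnitude is a design choice: the emulated
  observation is a "more than twofold" cell-type-specific overexpression
  with visibly large effect, and 4x places the plant several standard
  deviations above the twofold detection gate so the cell-type-specificity
  check is a property of the pipeline, not of sampling luck. A tenth of
  the distal background follows an iPSC program and a tenth an NPC
  program (days 7/10 near-identical), giving the clustering real
  structure.
* **Contacts.** Power-law decay (alpha 1) along the reference (control)
  or a 50:50 reference/derivative mixture (patient), flat trans level
  equivalent to 20 Mb separation, multiplicative enhancer bumps (x3),
  Poisson sampling (3e5 reads per viewpoint profile at 20-kb bins; 2e6
  read pairs per 100-kb matrix). The relocation screen uses a
  reciprocal translocation with seed-jittered, bin-aligned breakpoints
  moving enhancer clusters across derivatives.

The complete fixture (48-Mb genome, 400 genes, 100-kb matrices)
generates in a few seconds.

## Validation design and problem sizes

The acceptance experiments (mirrored in `tests/test_acceptance.py` and
recomputed by `scripts/acceptance.py`) use: 1,000 random events for
reconstruction/conservation/liftover (10^4 sampled bases per event);
2,000 genes x 20 seeds for the twofold rule's operating characteristics
at NB dispersion 0.05 and baseline mean 200; 500 seeded enhancer
relocations; 50 seeds for the NPC-only pattern. These sizes make every
stochastic estimate's Monte-Carlo error small relative to the margins
being checked, and the whole battery runs in tens of seconds.

One operating characteristic deserves an honest statement. The twofold
rule's sensitivity is evaluated both at effects planted exactly at 2x
and at 4x. At exactly 2x the measured log2 fold change is centred
exactly on the decision threshold, so the gate fires on ~50% of draws —
a property of any sharp threshold evaluated at its own boundary, not of
the implementation; replication cannot move it. At the stated noise
level (sd of log2 FC ≈ 0.2–0.25 at baseline mean 200, dispersion 0.05,
the emulated replicate depth) the rule reaches ≥95% sensitivity only for
true effects of roughly 2.7-fold and larger; at the 4x magnitude planted
for the positional gene it is ≈100%, with a false-positive rate on nulls
≈ 0.1%. Both numbers are reported by the acceptance script.

## What passing tests do and do not show

The simulations validate bookkeeping and inference mechanics —
reconstruction correctness, coordinate algebra, threshold behaviour,
planted-truth recovery — under a generative model that is deliberately
simple. Real data differ in ways the generator does not emulate:
mappability and GC artefacts in counts; shared per-gene biological
variation across replicates (the exon-sum construction makes multi-exon
genes less dispersed than a shared-gamma NB would; gene-level screens
therefore use single-unit genes so the stated dispersion applies
exactly); isoform complexity and ambiguous exon assignment; restriction-
fragment granularity, ICE-type biases, and A/B-compartment structure in
contact data; and breakpoints with microhomology or insertions. Passing
here means the pipeline does what it claims on data satisfying its
assumptions; it is not evidence about variant calling (junctions are
inputs) or about clinical interpretation, which remains out of scope.

## Known limitations

* Copy-number-neutral events only; duplications and circular derivatives
  are rejected with explicit errors, not modelled.
* One rearranged haplotype: the allelic mixture in contact calls assumes
  a single affected allele at fraction m.
* The 67/60/13/5-style counts are properties of the synthetic preset's
  topology, built to emulate a published event's figures; they are not
  re-derivations from that patient's (unpublished) coordinates, and
  annotation-dependent counts would differ on real data.
* 4C smoothing is off by default (a running-mean option exists); the
  caller operates on binned, not fragment-level, profiles.
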