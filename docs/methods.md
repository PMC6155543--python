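# Methods

This note documents the models and procedures implemented in `clonearch`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Clonal phylogenies and the Tree score

A clonal phylogeny is a rooted tree of clones. Each clone carries the
count of somatic mutations assigned to it and, optionally, a cell
fraction. Validation requires exactly one parentless clone, every parent
reference resolving, and connectivity (which, with unique parents, rules
out cycles). Clonal mutations are the root clone's; all others are
subclonal, so clonal + subclonal equals the total by construction.

The Tree score is

    T = 1 - (1/L) Σ_l d(l, root) / (N - 1),

with `N` clones, `L` leaves and `d` in edges. Properties relied on
throughout: every chain scores exactly 0 (its single leaf has depth
`N - 1`); the star attains the maximum `1 - 1/(N - 1)`; no topology on 1
or 2 clones can score above 0, so divergence is first expressible at 3
clones. For `N = 1` the formula is 0/0; the score is defined as 0, which
is continuous with the linear case (no branching is expressible). These
facts are verified in the tests against a brute-force path-enumeration
oracle over all rooted topologies up to 7 clones.

## Likelihood-weighted consensus

Candidate sets hold each sample's reconstructed trees with their
complete-data log-likelihoods (CDLL, natural log). The consensus:

1. sort by CDLL descending (stable — equal-CDLL candidates keep input
   order, a deliberate tie-break since no principled order exists among
   equally likely topologies) and keep `ceil(fraction × n)`, at least 1;
   default fraction 0.1 mirrors the common top-10% harvest;
2. min–max rescale the retained CDLLs to weights in [0, 1]. When all
   CDLLs are equal the formula is 0/0; all weights are set to 1, which
   reduces the weighted mean to the plain mean;
3. report weighted means of clone count, Tree score, clonal and subclonal
   counts. Outputs therefore lie in the convex hull of the per-candidate
   values.

Note the lowest-ranked retained tree always gets weight 0: it still counts
toward `n_candidates_used` but not toward the means. Trees with a
zero-mutation root are accepted (reconstruction tools sometimes emit a
non-cancerous root) and logged at debug level.

## Branching-process tumor model

Discrete time, synchronous generations. A cell with `k` accumulated
drivers dies with probability `d(k, s) = (1/2)(1 - s)^k`, replicates
otherwise; `s ∈ [0, 1)` is the per-driver fitness parameter. With `k = 0`
the process is exactly critical (expected offspring 1), which the tests
exploit as a calibration: the Monte-Carlo mean population must stay at its
initial value within sampling error.

On each replication, one of the two daughters mutates with probability
`μ`; a mutated daughter founds a new clone regardless of whether the
mutation is a driver or a passenger, so every non-root clone carries
exactly one private (founding) mutation. Two driver-probability
conventions are implemented, selected by `driver_mode`:

* `conditional_K` (default): P(driver | mutation) = `K`. `K = 0.025`
  corresponds to roughly 500 driver genes out of ~20,000, i.e. `K` as the
  *fraction* of mutations that are drivers.
* `conditional_K_mu`: P(driver | mutation) = `K·μ`, the literal product
  form. Under this reading drivers arise at rate `K·μ²` per replication
  and expansions essentially never occur at exome-scale mutation rates;
  it is provided for comparison, not used by default.

Cells within a clone are exchangeable, so the per-generation update is a
pair of binomial draws per clone (deaths, then mutants among
replications), keeping 10^5-cell populations desk-cheap. All randomness
flows from one seed; survival conditioning (on by default) retries
extinct runs on deterministically spawned child streams, up to
`max_attempts = 100`, and reports the attempts used so the conditioning
is auditable. Runs stop at `n_max = 10^5` cells or `g_max = 2000`
generations, whichever comes first — the model itself has no natural
stopping rule; these defaults allow multi-clone expansions at desk-scale
runtimes.

**Phylogeny extraction.** Clones holding ≥ 1% of the final population are
retained (the typical VAF detection floor of bulk exome sequencing). Each
retained clone re-attaches to its nearest retained ancestor. Private
mutations of a dropped clone are collapsed into its nearest retained
descendant — the clone whose cells still carry them — with ties going to
the larger, then lower-id, descendant so each mutation is counted once;
mutations of dropped clones with no retained descendant are discarded, as
sequencing of the final tumor would not see them. If the founder lineage
itself fell under the floor, the most recent common ancestor of the
retained clones is restored as the root: its (collapsed) mutations are
precisely the clonal ones shared by all surviving cells.

**Sweep scale.** The packaged sweep used in validation runs a 4×4
log-grid over `μ ∈ [10^-7, 10^-3]` and `s ∈ [10^-4, 0.5]` (the ranges
spanned by human-tumor estimates) with 10 replicates per cell at
`n_max = 2×10^4`, `g_max = 600`, 60 survival attempts. This keeps the
whole sweep around a few seconds while preserving the qualitative
structure: clone counts rise with `μ`, and multi-clone tumors are rarely
linear. Replicates whose attempts all went extinct are kept as rows with
missing statistics rather than silently dropped.

## Cohort metrics and instability classes

Mutation burden counts every variant row (no variant-class filtering, no
deduplication — each row is a variant). CNA burden counts segments with
mean log-ratio strictly above 0.3 or strictly below −0.3. Mean RMS is the
mean of ref+alt reads over mutated sites, missing for samples without
mutations. Purity/ploidy solution selection minimizes the unweighted
squared Euclidean distance to a reference pair, first-listed on ties.

Classes use strict inequalities on both axes (M: > 300 mutations and
< 80 segments; C: > 80 segments and < 300 mutations; MC: both high), so
boundary equality falls into Low — the measure-zero boundary absorbs into
the reference class rather than inventing a side.

The clone heatmap bins samples on `log(1 + count)` axes (natural log;
`+1` admits zero counts) normalized by the cohort maximum, 20 equal-width
bins by default; each cell holds the mean consensus clone count, with
empty cells missing rather than zero.

## Neutral-evolution fit

Under neutral growth the cumulative count of subclonal mutations with
VAF ≥ f grows linearly in 1/f. The fit restricts to the VAF window
[0.12, 0.24] — the window conventionally used with this model; above it
mutations are increasingly clonal, below it detection is unreliable —
evaluates M(f) at each observed in-window VAF, and regresses M on 1/f by
ordinary least squares with an intercept (configurable). R² > 0.98
(strict) classifies the sample as exhibiting neutral features. Samples
with fewer than 10 in-window mutations, or with a single support point,
are unevaluable (missing), not non-neutral. VAFs are raw
alt/(alt + ref); no purity or copy-number correction is applied at this
stage.

## Enrichment scan

Signature/alteration scores are binarized at "strictly positive"; the
carriers-vs-non-carriers comparison is a one-tailed two-sample Wilcoxon
rank-sum (Mann–Whitney) test — the only coherent two-group reading of a
"one-tailed Wilcoxon" between carriers and non-carriers — asking whether
carriers have *more* clonal (resp. subclonal) mutations. The exact null
distribution is used when the smaller group has ≤ 8 observations and the
pooled values are tie-free; otherwise the normal approximation with tie
and continuity corrections. The two branches agree within 10% relative p
outside the extreme tail (p ≳ 0.02); in the far tail the approximation's
relative error grows, as is standard.

FDR is controlled per tumor type by Benjamini–Hochberg (the procedure is
configurable only in threshold, not in method), separately for the clonal
and subclonal test families. Scores are −log10 p; classes C / S / CS
require the kind-specific score cut (2.5 for signatures ≈ p < 0.003; 3.0
for alterations ≈ p < 0.001), both configurable, and the q-values are
always emitted so other FDR framings can be re-derived. Feature × type
pairs with fewer than 3 carriers or no non-carrier are skipped with a
logged reason — exact tests on one or two carriers are degenerate.

## Synthetic-cohort generator

The generator's defaults are the study conditions the tests assume:

* **trees**: clones per sample uniform on 1–8; sequential attachment with
  `branching_tendency = 0.5` (attach to root with this probability, else
  extend the most recently added clone, so 0 gives a chain and 1 a star);
  per-clone cell fractions are Dirichlet(1.5) floored at 0.08 and
  renormalized, keeping every clone's expected VAF above the detection
  floor at realistic purity;
* **reads**: expected VAF = purity × CCF / 2 (diploid convention,
  deliberately no copy-number-aware multiplicity — CNA-aware VAF
  modelling belongs to the reconstruction tools themselves); depth
  Poisson with mean 100 (exome-like); purity Beta(10, 3) (mean ≈ 0.77);
  observed VAF < 1% dropped;
* **candidates**: 50 per sample (a scaled-down harvest); each applies
  Poisson(1) random edits (subtree regraft, clone merge, clone split),
  and its pseudo-CDLL is −5 per edit plus standard Gumbel noise — the
  Gumbel tail occasionally inverts ranks, exercising the weighting
  nontrivially, while the truth stays top-ranked in expectation;
* **burdens**: class targets drawn inside regions with margin to the
  300/80 boundaries (e.g. M: 450–2000 mutations, ≤ 60 altered segments)
  so detection-floor losses cannot flip a class; altered segments get
  |log-ratio| in [0.35, 1.5], neutral fill-in segments in (−0.25, 0.25);
* **features**: carriers Bernoulli(0.3); planted features resample
  carriers' clonal or subclonal targets as Poisson(effect × original)
  *before* trees and reads are generated, so every downstream view stays
  mutually consistent; an optional per-class clone-count shift
  (`class_clone_gradient`) plants the more-unstable-more-clones gradient
  when a test needs it.

What the generator does **not** emulate: copy-number-altered mutation
multiplicities, trinucleotide signature contexts, read-level sequence
data, sample contamination, or reconstruction error beyond the
tree-perturbation model. Passing tests therefore show the analysis
recovers planted structure under these idealized conditions, not that any
specific biological claim holds in real cohorts.

Two interactions are worth knowing: planted burden shifts move total
mutation counts, so they can legitimately move a carrier across a class
boundary (class round-trips are exact only without planted features), and
single-clone samples have no subclonal mutations for a subclonal effect
to act on.

## Pipeline and reproducibility

`run_pipeline` chains consensus → metrics/classes → neutrality →
enrichment over the interchange files, writes the per-sample and
enrichment tables, and records a manifest (seed, package version, every
effective threshold). Reruns with the same inputs and seed are
byte-identical. Config files reject unknown keys. The
reconstruction-accuracy flag takes a user-supplied read-depth vs
mutations-per-clone threshold curve per clone number; without one it
returns "ok" with a logged notice — no default curve is shipped because
published threshold lines are figure-derived, not printed values.

`scripts/acceptance.py` recomputes the two headline combinatorial facts
from scratch (the common Tree score of all chains with 2–50 clones, and
the minimal clone number admitting a positive score, by exhaustive
enumeration of rooted topologies up to N = 3) and writes them as JSON.

## Known limitations

* The simulator is non-spatial, has no copy-number events, and treats
  fitness as multiplicative in death probability only.
* Conditioning on survival from a single founding cell makes low-`s`
  parameter points expensive (survival of a critical line to generation g
  decays like 2/g); all-extinct replicates are reported, not retried
  forever.
* The consensus weighting assigns the worst retained candidate weight 0;
  with very few candidates this discards real signal.
* Neutrality fitting on few in-window support points is fragile; the
  10-mutation floor is a pragmatic, configurable guard.
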