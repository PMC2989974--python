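# Methods

`editevol` analyses the evolutionary dynamics of C-to-U RNA-editing sites in
plant mitochondrial protein-coding genes on a fixed, rooted phylogeny. This
note describes the models and procedures, the parameters that matter, the
synthetic-data generator, and the numerical and design choices made where
the design was genuinely open.

## Edited-site calling and exclusion

A site is *edited* in a taxon when the genomic DNA carries a C whose cDNA
reads T at the same alignment column; an alignment column is an edited site
when at least one taxon is edited there. Taxa whose cDNA is unavailable
contribute genomic states only (a genomic C without transcript evidence is
recorded as an unedited C with evidence "none", never inferred to be
edited; downstream operations may choose to treat such cells differently).
Columns where cDNA-verified taxa disagree about the editing status of their
C — edited in some, unedited C in others — are flagged heterogeneous and
excluded from every downstream count. A genomic T in another taxon is a
*loss* of the edited site, not heterogeneity, and does not trigger
exclusion. Gaps and `?` are missing data and never enter site counts.

The profile predictor scores each genomic C by the fraction of reference
protein sequences whose residue at that codon is matched exactly by the
edited amino acid but not by the unedited one (ties contribute nothing);
a C scoring at or above the threshold (default 0.6) is predicted edited.
This is deliberately a majority-identity simplification of comparative
editing predictors: no substitution-matrix similarity is used, and whenever
cDNA evidence exists it overrides predictions. Protein-level consequences
use the standard genetic code (plant mitochondria use it) and the
Kyte–Doolittle hydropathy scale; each edit is evaluated in isolation within
its codon.

## Parsimony mapping of editing characters

Edited sites form binary characters (1 = edited C present, 0 = T or
unedited C, missing = `?`). Minimum change counts come from a unit-cost
Sankoff dynamic program, which equals Fitch parsimony on binary data and
handles polytomies and missing tips without special cases; missing tips are
treated as the full ambiguity set {0,1} rather than dropped, keeping branch
sets comparable across characters. The exact MPR (most-parsimonious
reconstruction) state set of every node is computed from subtree plus
"rest-of-tree" costs and reported wherever it contains more than one state
— including the root, whose ambiguity is reported rather than silently
fixed.

Ambiguity is resolved by a preorder backtrace with exact cost-to-go, so any
resolution spends exactly the minimum number of changes. Ties between
keeping and changing the parent state are broken by the optimization mode:
**DELTRAN** (the default) keeps the parent state, delaying changes toward
the tips and therefore favouring parallel losses; **ACCTRAN** switches away
from it, accelerating changes toward the root and favouring an early loss
undone by a later regain. A tie among root states resolves to state 1 (the
edited condition), which is what lets DELTRAN place parallel losses below.
Both resolutions are verified against full enumeration of the MPR set on
small trees in the test suite. Tree statistics follow the usual
definitions: L is the summed minimum length; CI = Σ(min steps)/Σ(length)
over parsimony-informative characters only (autapomorphies excluded);
RI = (Σg − L)/(Σg − Σm) with g the tree-independent maximum steps.

Gains are scored at the DNA level (T→C at an edited column) even without
cDNA confirmation of the restored site's editing status, mirroring the
admitted overestimation this implies; the heterogeneity filter removes the
confirmed disagreements.

## Ancestral sequences and synonymous rates

Nucleotide sequences at internal nodes are reconstructed per column by
4-state parsimony with DELTRAN resolution (the primary method); columns
containing any gap or ambiguity in any taxon are masked and excluded from
reconstruction and event counting. An optional ML variant performs marginal
reconstruction under a single-rate HKY-like model (κ = 2, empirical base
frequencies); because input trees may carry branch lengths in time units,
the ML variant first rescales lengths to expected substitutions/site using
a Jukes–Cantor-corrected mean pairwise distance calibration.

Per-branch synonymous divergence uses Nei–Gojobori-style counting between
the reconstructed ancestor and descendant: synonymous site fractions per
codon (averaged over the two codons; mutations to stop codons count as
nonsynonymous), observed differences averaged over all mutational pathways
(pathways through stops are dropped when a stop-free pathway exists), and
dS = −(3/4)·ln(1 − (4/3)·p_s). Synonymous proportions at or beyond 3/4
raise a saturation error. This counting estimator deliberately replaces a
full codon-likelihood fit: the downstream analyses use ranks, ratios and
correlations of dS, for which parameter recovery on synthetic data (tested)
is the relevant standard, and a hook for an external codon-ML engine
remains a natural extension. Positions with more than one MPR state
contribute fractionally to event counts (uniform weight over the states at
each branch endpoint); a strict integer-only mode exists.

C→T changes at third codon positions — always synonymous under the
standard code, a property asserted in the tests — are extracted per branch
from the same reconstructions, excluding edited-site columns, and form the
neutral reference class. The relative-rate test is Tajima's 1D test
restricted to third positions, with an exact two-sided binomial p at
probability 1/2; the named statistic is our choice, since only a "pairwise
relative rate test" is specified by the upstream protocol.

## Dating and absolute rates

Node ages come from non-parametric rate smoothing (NPRS): minimise
Σ over internal nodes of Σ over child branches (r_parent − r_child)², with
the root contributing the variance of its children's rates around their
mean, where r = branch length / branch duration. The root age is fixed by
calibration (default 130 Ma); tips sit at age 0. Ages are parameterised as
fractions of the parent age (bounds [1e-4, 1−1e-4]), giving monotonicity
by construction, and optimised with L-BFGS-B from a
path-length-proportional start plus four randomly perturbed restarts
(perturbation σ = 0.05 on the fractions, seeded); the best objective is
kept. Durations are floored at 1e-6 × root age to keep rates finite. On
ultrametric input the start point is already exact, so the clock limit is
recovered to machine precision.

The absolute synonymous rate of a taxon is
R_S = (Σ dS over the focal-node→tip path) / (focal age in years), with the
focal node's smoothed age or an externally supplied calibration (default
79.1 Ma for the focal ancestor) in the denominator. This node-to-tip form
sidesteps the many zero-length single-gene branches that make per-branch
rates unstable. Note the upstream protocol is internally inconsistent about
the dating engine (rate smoothing in its methods, penalized likelihood in
its results); this package implements NPRS and treats the focal-node age as
a configurable constant.

## Comparative statistics

The ES-vs-3rd comparison table gives, per taxon, the proportion of
focal-ancestral edited sites lost along the focal→tip path (denominator:
characters reconstructed as edited at the focal node) and the proportion of
focal-ancestral 3rd-position C's that underwent C→T on the same path
(denominator: C-bearing third positions in the reconstructed focal
sequence). The denominator convention is a documented choice — the
published table layout does not state one — selected because it reproduces
the definitional anchors (all ancestral sites lost → rate 1.0; none → 0).
Each taxon's 2×2 (changed/unchanged × ES/3rd) is tested with Fisher's exact
test, two-sided by the sum-of-smaller-probability convention.

Sister-clade contrasts: each branch variable is propagated to a node-to-tip
value (tip branch → its own value; internal → own value + mean of
daughters, recursively); every binary internal node contributes the
difference of its daughters' node-to-tip values, oriented so Δx ≥ 0, and
the association is summarised by regression through the origin
(slope = Σxy/Σx², r = Σxy/√(Σx²Σy²), p from t = r√((n−1)/(1−r²)) on n−1
df). Felsenstein's independent contrasts use branch *durations* (ages of
splits) as variances — the age standardization — with the usual pruning
variance augmentation; polytomies are resolved by sequential pairing with
zero-length connectors. Contrast sets default to gains+losses as the
"changes" variable, with a losses-only flag.

Because taxa that have already lost every edited site cannot lose more, a
pruning variant collapses each maximal all-zero-edit clade to a single
representative (longest or shortest terminal branch) before contrasts are
recomputed.

## Retroprocessing scan

Retroprocessing (gene conversion by a reverse-transcribed, edited cDNA)
predicts simultaneous loss of many edited sites in a contiguous stretch.
For each branch with at least 3 losses, the scan computes, for every
subset size k from 3 to the number of losses, the tightest window
containing k losses, and compares each against a permutation null that
redraws the same number of losses uniformly (without replacement) from the
branch's at-risk edited sites (those still edited in the branch's parent).
Because the scan minimises over k, the final p-value is the min-p
calibration: every permutation's own min-over-k rank statistic forms the
reference distribution, which keeps the branch-level false-positive rate at
the nominal α (verified ≈ 0.04–0.05 at α = 0.05 in the tests). A branch
that loses *every* at-risk site is reported as a whole-gene conversion
candidate (the permutation null is degenerate there). Defaults: 10,000
permutations, α = 0.05, seeded. This statistic is our formalisation of a
qualitative clustering argument; single-site "microconversion" is out of
scope.

## Synthetic data

The generator emulates the study conditions: a Yule tree scaled to a
130-Ma root with 46 taxa by default; five genes totalling ~4356 aligned
positions with edited-site counts {5, 44, 25, 30, 25} (atp1, ccmB, cob,
mtt2, nad5) placed at 1st/2nd codon positions in a 50/50 mix (3rd-position
editing is vanishingly rare and not simulated); per-site HKY-like
substitution (κ = 2) with 1st/2nd positions evolving at 0.3× the
3rd-position rate (default 5×10⁻⁴ subs/site/Myr, giving tip R_S values in
the 10⁻¹⁰–10⁻⁹/site/yr range observed in these genes); clade-specific rate
multipliers for lineage effects; and retroprocessing events that convert a
branch's remaining edited C's to T (whole gene or a window, with a
completeness probability allowing partially edited cDNA templates). The
edited-site C→T hazard is λ_ES × the 3rd-position C→T baseline — the
1st/2nd site-rate scaling is divided out at edited sites so the generating
ES:3rd hazard ratio is exactly λ_ES/λ_3rd. cDNA is derived from DNA by
rendering every still-edited C as T (noise-free transcripts). All
randomness flows from one seed; the ground truth records the true tree
with ages, every node sequence, the complete mutation log (replayable to
byte-identical sequences, and tested), per-node editing status and all
conversion events.

What the generator does **not** emulate: indels and alignment error,
selection on amino acids, partial/tissue-variable editing levels in the
cDNA (conversion completeness is the only partial-editing knob),
among-site rate heterogeneity beyond the position classes, and base
composition drift. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to alignment or transcript noise.

The recovery harness re-estimates the λ_ES/λ_3rd ratio through the full
call → filter → map → reconstruct → count chain with an exposure-weighted
event-rate estimator: parsimony-mapped events divided by at-risk site-time
(a site is at risk on a branch while its reconstructed parent state still
carries the C). This corrects for sites already lost along deep paths and
is close to unbiased over true ratios 1–10 in the tested regime (30 taxa,
40 edited sites, ~200 third-position C's, ~0.03 expected C→T per 3rd-site
per root-to-tip path).

## Problem sizes and numerical conventions

The test suite runs the acceptance-grade studies at 200 replicates per
ratio for the rate-ratio recovery, 50 replicates for dating accuracy
(20 taxa, log-normal rate drift σ = 0.2), 500 replicates for PIC
correlation recovery (30 taxa) and for the retro-scan null, completing in
about 2–3 minutes on one CPU; `scripts/acceptance.py` uses moderately
smaller replicate counts (e.g. 100 per ratio) and finishes in about a
minute. Alignment columns are 0-based internally and 1-based in all
reports; codon position = column mod 3 + 1. Child order within a node,
branch identifiers and all TSV float formats are deterministic, so
identical inputs and seed give byte-identical outputs (tested).

## Known limitations

Parsimony undercounts multiple hits, so the ratio estimator drifts low
(−10–15%) at λ_ES/λ_3rd = 10 in deep trees; the dS counting estimator
shares the usual NG86 biases at high divergence and refuses saturated
pairs rather than extrapolating; NPRS is a smoothing heuristic, not a
model-based clock, and inherits its known tendency to compress node ages
under strong rate autocorrelation; the edit caller trusts cDNA absolutely
(no sequencing-error model); and the retro-scan null conditions on the
observed at-risk positions, so clustering that is already present in the
at-risk set (rather than in the losses) is, by design, not signal.
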