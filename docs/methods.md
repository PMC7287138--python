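# Methods

## The analysis in brief

The package studies rate heterogeneity of the trans-spliced plastid
*rps*12 gene in a phylogenetic framework. Given a fixed rooted topology, a
codon alignment of the spliced gene and per-taxon gene structure
(intron-II presence, exon regions), it:

1. splices and partitions the gene (SC codons 1–38; IR codons 39–123 plus
   the terminal stop, which is removed before likelihood work);
2. fits codon (MG94×HKY85) and nucleotide (HKY85) substitution models by
   maximum likelihood on the fixed topology;
3. converts the fitted phylogram into a chronogram by penalized-likelihood
   rate smoothing under a single fixed root calibration;
4. divides per-branch dS and dN by branch durations to obtain absolute
   rates R_S and R_N (substitutions/site/My), and derives per-branch
   expected transition/transversion counts from a per-branch-κ HKY fit;
5. compares these quantities between intron-containing (type I) and
   intron-less (type II) branch classes, and between SC and IR exon
   regions, with Wilcoxon rank-sum tests and df=1 likelihood-ratio tests.

## Substitution models

**HKY85.** Instantaneous rate i→j proportional to π_j, multiplied by κ for
transitions; normalized so −Σπ_iQ_ii = 1, giving branch lengths in expected
substitutions per site. κ can be shared, class-specific (one per branch
class), per-branch ("local parameters": each branch has its own κ and
length), or per region in partitioned fits.

**MG94×HKY85.** State space: the 61 sense codons of NCBI translation table
11 (its codon→amino-acid map coincides with the standard code). Rate
between codons differing at exactly one position is proportional to the
position-specific frequency of the target nucleotide (F3×4), ×κ for
transitions, ×ω for nonsynonymous changes; multi-step rates are zero. With
stationary distribution ∝ the product of positional frequencies restricted
to sense codons, detailed balance holds exactly. Zero positional
frequencies are floored at 1e−10 (per position, then renormalized), which
keeps the stationary vector the exact product measure and never produces
log(0) for unobserved codons.

**Branch-length decompositions.** The expected flow of the normalized
generator splits into synonymous and nonsynonymous parts; dividing each by
the corresponding *neutral* (ω = 1) flow proportion yields dS and dN per
branch (the mutational-opportunity convention), so that dN/dS = ω exactly
and dS = dN = t when ω = 1. For HKY85, TI = t × (transition share of the
stationary flow) and TV = t − TI.

**P(t).** Matrix exponentials use the symmetric similarity transform
available for reversible generators (eigendecomposition of
D^{1/2}QD^{−1/2}), with a scaling-and-squaring fallback for degenerate
frequency vectors; rows are clipped/renormalized against round-off.

## Likelihood machinery

Felsenstein pruning over compressed site patterns with per-node scaling
(log-scalers accumulated per pattern), so deep trees cannot underflow.
Ambiguous or gapped cells contribute a partial likelihood of 1 over all
states (missing data). Branch lengths are optimized coordinate-wise by
bounded Brent searches in [1e−9, 20] substitutions/site — each branch's
one-dimensional likelihood uses inside/outside conditional arrays, so one
proposal costs a single matrix product — interleaved with bounded
L-BFGS-B updates of the global parameters in log space (κ, ω bounds
[1e−4, 1e3]); a round that improves lnL by less than 1e−8 terminates the
fit, and the converged flag records whether that happened within the round
budget. Hitting the upper branch-length bound sets a saturation flag in
pairwise estimates. Input topologies carrying time-scaled lengths are
rescaled into the search box before fitting (a fit started at hundreds of
substitutions/site would sit at stationarity with no usable gradient).

Partitioned fits (SC vs IR) share branch lengths and κ across partitions
and add a free relative-rate multiplier per extra partition; the two-rate
model then adds exactly one parameter (the second ω or κ), making the
region LRTs df=1. The same df=1 structure applies to the branch-class LRTs
(one shared ω or κ vs one per class). LRT p-values come from the χ² upper
tail.

Pairwise estimates (used for the exon-region comparison against outgroups)
maximize the two-sequence likelihood over (t, κ, ω) — or (t, κ) for the
nucleotide model — from codon- or nucleotide-pair counts, then decompose t
into dS/dN or TI/TV.

The nonparametric bootstrap resamples codon columns with replacement,
refits branch lengths with model parameters held at their estimates
(defaults: 100 replicates), and reports the standard deviation across
replicates; dS/dN standard errors are scaled from total-branch-length SEs.

## Dating

Node ages and per-branch rates minimize a Poisson-likelihood-plus-penalty
objective: branch substitution counts x_b = length_b × nsites with mean
r_b·Δt_b·nsites, plus λ times the sum of squared rate differences over
ancestor–descendant branch pairs (root children contribute their rate
variance). Rate differences are measured relative to a global rate scale
derived from the data, so λ is dimensionless: with raw plastid-scale rates
(~1e−4–1e−3 substitutions/site/My) an unnormalized quadratic penalty would
be numerically invisible and the ages unidentified, and the normalization
also makes the solution scale exactly with the root calibration at fixed λ.
λ defaults to 1.0; leave-one-terminal-out cross-validation over a λ grid is
available (each tip's Poisson term is dropped, its count predicted from the
parent branch's fitted rate, and the χ²-style prediction error summed).

Ages are optimized in a transformed space — each internal node's age is a
logistic fraction of its parent's age, tips fixed at 0, the root fixed at
the calibration (default 354 My) — so parent > child ordering holds by
construction. Optimization is L-BFGS-B from a deterministic clock-like
start plus seeded random restarts (5 by default; best objective kept).
Zero-length branches are floored at 1/(2·nsites) substitutions before
forming counts. Only the single fixed root calibration is supported;
min/max node constraints and outgroup handling are configuration concerns
upstream (the topology handed to the dater is taken as given).

Bootstrap node-age SEs rerun branch-length refitting and dating per column
resample (default 100 replicates); replicates that fail are dropped and
counted. The root's SE is 0 by construction.

## Statistical comparisons

Wilcoxon rank-sum: the exact null distribution of the rank sum is
enumerated when n+m ≤ 16 and the pooled sample is tie-free (two-sided p =
twice the smaller tail, capped at 1); otherwise the tie-corrected normal
approximation with continuity correction is used. The SC-vs-IR comparison
is run unpaired by default to match the named test of the comparative
design, although rows pair per (taxon, outgroup); a paired signed-rank
option exists behind a flag and logs its use. Pairwise rows against
multiple outgroups are kept separate, not averaged. Branches with
Δt < 0.1 My are flagged and excluded from rate ratios rather than divided
(threshold configurable). Raw p-values are reported; Holm adjustment is
available behind a flag.

## Synthetic data

The generator emulates the study system: an ultrametric tree with the root
at 354 My (birth-death via dendropy — terminal branches are padded past the
final speciation so all durations are positive, and the draw is
deterministically re-seeded until the requested type-II clades exist —
or balanced/ladder shapes); designated intron-less clades labeled type II
including their stem branches; codons evolved along the tree under the
branch-class MG94×HKY85 models (root drawn from the F3×4 stationary
vector); and toy plastome-like records embedding exon 1 in an LSC context
and exons 2–3 as exact reverse-complement IR copies, with a 200-nt spacer
standing in for intron II in type-I taxa (intron sequences are never
analyzed, only exercised by the coordinate handling).

Defaults are the study conditions: 16 taxa, 124 CDS codons (123 sense
codons + TAA stop appended by the emitter; stops are outside the simulated
state space), 38 SC codons, two type-II clades (sizes 3 and 2, mirroring
the two independent intron losses), ω = 0.1 and κ = 2 for both classes (a
conserved ribosomal protein), AT-rich positional frequencies, strict clock
at 5e−4 substitutions/site/My (a plastid-typical rate; it converts ages in
My to expected substitutions), root age 354 My. Optional dials: a lognormal
relaxed clock (σ = 0.3; multipliers have mean 1), a branch-length
multiplier on IR codons (the region effect), and an absolute-rate
multiplier per branch class (plants R_S/R_N shifts). Everything is
reproducible byte-for-byte from (config, seed).

What the generator does *not* emulate: indels and alignment uncertainty,
gene conversion between IR copies, base-composition heterogeneity among
lineages, and selection regimes beyond a single ω per branch class. In
particular, a single region multiplier moves dS, TI and TV of a region
together, so the real-data pattern of IR-higher dS *jointly with* SC-higher
TI/TV cannot be planted in one simulation; directional recovery of each
effect is therefore checked in separate simulations. Passing tests
demonstrate correctness and calibration of the machinery under the model
family, not robustness to these real-data complications.

## Problem sizes used in the checks

The test suite and acceptance script run at deliberately modest sizes
chosen to make the statistical checks sharp but cheap: exactness of the
pruning likelihood on trees of ≤ 4 tips × ≤ 5 sites against brute-force
enumeration (50 random draws, 1e−10 tolerance); parameter recovery (κ, ω
per class within 10%; node ages within 5% median relative error) on
16-taxon, 2000-codon simulations; LRT and Wilcoxon type-I error over 200
null replicates at 8 taxa × 300 sites; directional recovery of planted
effects over 10 replicates each (3× class-rate effect at the standard gene
size; 2×/0.5× region effects at 600 codons per region, where per-region
pairwise estimates are informative).

## Known limitations

- Branch-length optimization is coordinate-wise with inside/outside arrays
  refreshed per sweep; it is robust but not the fastest scheme for large
  trees (hundreds of taxa).
- The dating objective treats substitution counts as Poisson with
  real-valued counts (lengths × sites), ignoring estimation covariance
  between branches; bootstrap SEs capture that variation empirically.
- The exact Wilcoxon path enumerates C(n+m, n) rank subsets and is
  restricted to n+m ≤ 16; beyond that the tie-corrected normal
  approximation is used.
- Per-branch κ fits ("local parameters") on short alignments are weakly
  identified; their TI/TV values are best treated comparatively, as in the
  class-level rank tests, not as precise per-branch estimates.
- No among-site rate variation (gamma) in either the likelihood or the
  dating stage, and no codon site-models beyond branch-class ω.
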