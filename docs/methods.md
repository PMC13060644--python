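# Methods

## Scope and model of the data

`combiphos` implements the computational analysis of a multiplexed
drug-combination (phospho)proteomics experiment: up to 18 samples barcoded with
TMTPro isobaric labels are quantified as reporter-ion intensities per channel,
possibly across several injection runs of the same pooled sample.  The
statistical model underlying every stage is multiplicative: the reporter
intensity of feature *f* (a phosphosite or a protein) in channel *c* of run *r*
is treated as

    log2 A_{f,c,r} = mu_f + delta_{f, cond(c)} + bias_{r,c}
                     + slope_{r,c} * (mu_f - mean mu) + noise

with a feature baseline `mu_f`, an additive (log2) treatment effect `delta`
per condition, a per-channel systematic bias, an intensity-dependent distortion
(slope per log2-intensity unit), and log-normal measurement noise.  Unquantified
reporter ions are reported as 0 by the upstream search engine; a 0 or blank
cell is therefore stored as missing and no downstream operation ever sees a
zero intensity.  Nothing is imputed.

## Normalization chain

1. **Reference channel.** Within each multiplex the reference is the channel
   with the highest mean pairwise-complete Pearson correlation of log2
   intensities with all other channels (ties break by channel order).  A user
   override is accepted for workflows that fix the reference per run.
2. **Rank-invariant pairwise correction (IRON-style).**  Each channel is
   corrected against the reference using features whose ranks agree between the
   two channels.  The invariant set starts from all pairwise-complete features
   and shrinks by halving a rank-difference tolerance `t` from 0.5 (keep
   features with |rank difference| <= t*n, ranks recomputed within the current
   set) until the set changes by < 1% or would fall below
   max(20, 5% of the pairwise-complete count).  `mode="global"` subtracts the
   invariant set's median log2 ratio; `mode="curve"` (default) subtracts a
   running-median curve of log2 ratio vs mean log2 intensity
   (window max(11, 10% of the invariant set), knots at window centres, linear
   interpolation, flat extrapolation), re-centred so the invariant-set median
   residual is ~0.  If the invariant set collapses below the minimum the
   pairwise fit falls back to the global mode with a logged warning.  This
   algorithm is this package's own concrete, documented normalization; it is a
   rank-invariant scheme of the IRON family, not a re-implementation of any
   particular binary.
3. **Computational pools and bridging.**  Each run's pool is the per-row
   geometric mean over non-missing channels (skip-missing is a deliberate
   choice; requiring complete rows would discard most phosphosites at realistic
   missingness).  Run abundances become ratios against their pool, pools are
   normalized together against their median pool, each row's pool mean `M_f`
   (geometric mean of normalized pools across runs) is stored, and ratios are
   scaled back by `M_f`.  Algebraically the per-row geometric mean of ratios is
   exactly 1 and within-run channel contrasts are untouched; only run-level
   systematic differences move.
4. **Collapse.**  log2 transform, then the arithmetic mean of log2 values over
   a sample's injection replicates, missing values skipped.

**Idempotence.** Applying the global-mode normalization twice leaves
second-pass corrections at 0 to < 1e-6 log2 units, and the curve mode is
exactly idempotent in the noiseless identity/global-shift cases.  On noisy
data the curve mode is only approximately idempotent: a second running-median
fit re-estimates residual noise at the order of noise_sd/sqrt(window), which is
why the strict idempotence guarantee is stated (and tested) for the global
mode.

## Differential scoring

Per feature and contrast (numerator condition vs denominator): the log2 ratio
is the difference of condition means over biological replicates; the p-value is
a two-sided unequal-variance Welch t-test on the per-sample injection-averaged
log2 values (n = 3 per condition by default); the priority score is
`S = sign(delta) * sqrt(|delta| * -log10 p)`.  Cutoffs are strict:
phosphosites pass at |delta| > 1 (2-fold) and p < 0.05, protein expression at
|delta| > 0.585 (1.5-fold) and p < 0.05.  Raw p drives selection — this
mirrors the filtering convention of the workflow the package reproduces — and
a BH-adjusted column is emitted for information only.  Zero-variance
degeneracies (possible at n = 3) are flagged: equal means give (t=0, p=1),
unequal means give the smallest positive double rather than a silent 0.

Row ordering brings the strongest signals to the top: number of passing
contrasts (desc), max |S| across contrasts (desc), positive direction first at
the deciding contrast, then feature id.  The tie-breakers beyond the first key
are this package's deterministic completion of an under-specified convention.

## Bliss synergy

Effects are fractions affected relative to vehicle, `f = clamp(1 - v%/100, 0, 1)`
— the standard Bliss convention.  Expected combination effect
`E = fA + fB - fA*fB`; `dBliss = f_obs - E`; classes: synergistic > 0.05,
antagonistic < -0.05, additive in between (boundaries inclusive to additive).
Replicates are averaged on the viability scale before scoring (matching how
such grids are usually plotted, mean ± SD); per-replicate dBliss values are
emitted alongside for transparency.  Single-dose designs (one dose of drug B
crossed with a titration of drug A) are ordinary 1×k grids.

## Network prioritization

The interaction graph is the induced subgraph over significant features'
gene symbols, edges gated at combined score >= 0.15 (the "low confidence"
STRING threshold), used unweighted.  Betweenness is unweighted shortest-path
betweenness with each unordered pair counted once; the normalized variant
divides by (n-1)(n-2)/2.  Communities come from deterministic greedy
modularity maximization (isolated nodes are singletons).  Each node's fold
change is the log2 ratio of its strongest (max |delta|) passing feature for
the chosen contrast, phosphosite evidence preferred over expression; the
priority rank is the descending product of normalized betweenness and
|fold change|, ties broken by larger |fold change| then node name.  Computing
centrality on the induced subgraph (rather than a larger neighbourhood) and
the max-|delta| site-to-gene summary are documented package choices where the
convention is genuinely open.

## Over-representation

One-sided hypergeometric upper tails (`P(X >= k)`), exact `math.comb`
summation for backgrounds up to 1000 genes and the scipy survival function
above, Benjamini–Hochberg step-up adjustment across sets, selection at
adjusted p < 0.05.  The background is the quantified universe, not the genome.
This is a standard Fisher ORA, not DAVID's jackknifed EASE variant — a
deliberate simplification.

## Synthetic data: what it emulates and what it does not

The TMT generator reproduces the design features the analysis must survive:
6 conditions × 3 biological replicates in one 18plex (vehicle, single agents,
combinations — the condition list is configurable), injection runs that share
sample truth but draw independent channel bias/distortion/noise (exactly the
batch structure pool-bridging removes), log-normal noise (sd 0.25 log2 units),
per-channel bias (sd 0.3), distortion slopes within ±0.03 per log2 unit, 10%
responsive features at |delta| = 2, and intensity-dependent missingness
(dropout probability logistic in the true log2 intensity, midpoint 15,
steepness 1 — about 1% dropout at the baseline mean of 20 and ~50% for
features 5 log2 units below it).  It does **not** simulate spectra,
peptide-to-protein inference, or TMT ratio compression from reporter-ion
interference; passing tests therefore demonstrate correctness of the
statistical chain, not robustness to co-isolation artefacts.

The dose-response generator uses Hill inhibition curves per drug and defines
combination truth on the fraction-affected scale with an additive interaction
term ε, so the downstream dBliss estimate identifies ε exactly absent noise
and clamping (cells pushed to f = 1 are clamped; recovery checks use
unclamped cells).  The network generator grows a connected scale-free backbone
(Barabási–Albert), plants dense modules (default two of 10 nodes at
intra-module edge probability 0.8) and wires a designated hub to half of all
nodes so hub identity is an unambiguous planted truth.

Community-recovery checks use a pre-registered pairwise-agreement bound of
0.8 on planted nodes, calibrated on the generator across seeds before the
tests were frozen.

## Problem sizes and numerical choices

Default analyses run at 2000 features × 18 channels × 2 runs; the type-I-error
check uses a null simulation of the same size, where the empirical fraction of
p < 0.05 is expected in [0.03, 0.07] (binomial tolerance at 2000 features,
with Welch at n = 3 slightly conservative).  Monte-Carlo synergy checks use 20
independent grids.  Floating-point contracts: reporter tables round-trip
bit-exactly (%.17g formatting and exact strtod parsing); pool-ratio geometric
means equal 1 to 1e-9 log2; bridging preserves within-run channel ratios to
relative 1e-12; identity and pure-scale normalization recover the reference to
1e-9 log2.

## Known limitations

- The curve-mode correction is not idempotent on noisy data (see above).
- Raw p drives feature selection; at 2000+ features this is a deliberate
  reproduction of the target workflow, not an endorsement — the emitted BH
  column should be preferred for new designs.
- Phosphosite keys must be pre-resolved upstream (one row per site); ambiguous
  localization is out of scope.
- Betweenness is computed on the induced subgraph of significant proteins;
  ranks can differ from a computation on a larger interactome neighbourhood.
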