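# Methods

## One-cycle life-history model

A culture founded by `P0` propagules grows hyphal biomass exponentially
at specific rate `r_h` (h⁻¹) until the conidiation onset `t_c`, then
produces conidia linearly on the frozen biomass at rate `r_c` (conidia
per hyphal unit per hour) until the transfer at `T` (default 24 h,
matching a daily regime). A fraction `f ∈ [0, 1]` of hyphae fragments
into suspended transferable particles:

    H_T = P0 · e^(r_h · t_c)
    C_T = r_c · H_T · (T − t_c)
    P_T = f · H_T + C_T

All counts are real-valued expectations; integerization happens only in
the simulator. Fragmentation does **not** deplete the biomass available
for conidiation (C_T uses the full H_T, not (1 − f)·H_T); the
alternative bookkeeping would shift the optimum toward earlier onset at
high f but is not what the census equations above state.

**Optimal onset.** dP_T/dt_c = P0·e^(r_h t_c)·[r_h f + r_c(r_h(T − t_c) − 1)].
The bracket is strictly decreasing and linear in t_c, and the
exponential prefactor is positive, so P_T is unimodal on the real line
with interior root

    t_c* = T + f/r_c − 1/r_h.

Clamping the root to [0, T] therefore yields the constrained argmax
exactly: left of the root P_T increases, right of it P_T decreases.
Stated conventions for the degenerate limits, each covered by a test:
`r_c = 0, f > 0` → onset `T` (fragments are the only route and ride the
exponential); `r_h = 0` → onset `0` (no benefit to delaying when hyphae
cannot grow); `r_c = 0, f = 0` → error (P_T ≡ 0, no optimum exists).
The brute-force oracle grids t_c (default 10⁻³ h), evaluates P_T
directly, and breaks ties toward the earliest onset; the suite asserts
closed-form/oracle agreement over 1000 random draws and agreement of
the census with small-step Euler integration to 0.1 %.

In the equal-rates case r_h = r_c = r the optimum reduces to
T + (f − 1)/r: later onset is favored by more fragmentation and, for
f < 1, by faster rates, and f = 1 abolishes conidiation — the onset
surface export reproduces this monotone structure.

## Serial-dilution simulator

Each bout applies the deterministic census per genotype (P0 = current
count, T = regime period), caps **summed hyphal biomass** at a carrying
capacity K by proportional rescaling across genotypes (no within-cycle
resource model is attempted; the cap is the simplest saturation that
preserves relative genotype shares), then transfers a 1/D volumetric
aliquot. Transfer sampling is Poisson with mean `census_total / D`:
propagules dilute independently in a well-mixed aliquot, and counts are
far larger than the sample so hypergeometric corrections are
negligible. A deterministic mode rounds the expectation half-to-even
instead. Extinction is recorded at the first transfer carrying zero
propagules; extinct populations stay extinct.

With sub-unit per-capita transferable yield y = e^(r_h t_c)(f +
r_c(T − t_c))/D the expected census declines geometrically, so the mean
extinction transfer is ≈ ln(N0)/ln(1/y); the suite checks this within
±1 transfer over 200 seeds (the Poisson branching tail biases the
observed mean slightly late, which the ±1 band absorbs). Supercritical
populations plateau at a transferred count near K·(f + r_c(T − t_c))/D,
the cap fixed point.

**Evolutionary mode.** Mutation acts per transferred propagule (a
genotype-granular supply; per-cell-division events would be
indistinguishable at these census sizes but far costlier to simulate):
each transferred propagule mutates with probability µ, drawing a new
genotype with t_c perturbed by a reflected Gaussian step inside [0, T]
and/or f by a Gaussian step on the log-odds scale. Selection is
emergent — genotypes closer to the optimum yield more propagules per
capita, and the bottleneck does the rest.

Default study conditions for the recovery experiment: r_h = r_c =
0.3 h⁻¹, f = 0.5, T = 24 h, D = 100, K = 2·10⁵ hyphal equivalents
(transferred population ≈ 2·10³, keeping runs seconds-fast while large
enough that drift does not swamp selection), µ = 10⁻² per transferred
propagule, t_c step sd 1 h, 300 transfers, founding count 100. Under
these conditions the population-mean onset converges from t_c = 12 h to
within the mutation-kernel width of t_c* = 22.33 h in every one of 20
seeded replicates.

**Generations.** Regrowing a D-fold diluted culture takes log2(D)
doublings, so a 1:100 bout contributes log2(100) ≈ 6.64 generations.
Printed totals depend on rounding, so the rule is an explicit parameter:
`one-decimal-floor` (per-bout value floored to one decimal — 85 bouts
give 85 × 6.6 = 561), `nearest-ten` (exact product rounded to tens —
45 → 300, 85 → 560), or `exact`.

## Expression pipeline

Inputs are a locus × sample FPKM TSV over ancestor/derived genotypes at
18, 22, 24 h in replicate, and a locus → GO-slim term TSV. Replicates
are averaged before any transform (the duplicate design is not modelled
as a factor — normalization is defined on the six genotype × time
values per locus). Each cell is transformed as log(x + 1) — natural
log; log2 is reserved for fold changes — and divided by the locus's
six-cell sum, giving shares that sum to 1 and preserve the direction of
expression changes. All-zero loci get zero shares and a flag. The
fold-change filter operates on replicate-mean FPKM with a configurable
pseudocount (default 0.1 FPKM) guarding zero denominators, keeping loci
with |log2 FC| > 1 at one or more timepoints.

**Global fit.** Mean shares over each GO term's member loci form a
G × 2 × 3 cell table (multi-membership loci contribute to every term
they map to, mirroring GO slim mapping; no down-weighting). The OLS
model `share ~ GO + genotype + time + GO:genotype + GO:time` on those
6G cells has model df 4G − 1 and residual df 2G — the residual pools
the genotype:time and GO:genotype:time strata. The df pair is a design
constant ((111, 56) at G = 28); F and adjusted R² are data-dependent
and are reported, never asserted against external values. The df
identity is inferred from that subscript structure, which implies a
cell-mean (not locus-level) response; that inference is a documented
modelling choice. Empty terms are dropped with a warning. A constant
response would make the F ratio 0/0; it is reported as F = 0, adj
R² = 0.

**Per-GO tests.** Whether group-level calls should come from global
contrasts or per-group models is genuinely open; we test per group, at
locus level: each term's member-locus shares enter a balanced two-way
fixed-effects ANOVA (genotype, time, genotype × time) with loci as
replicates. The genotype main effect yields the *directional* call, the
interaction the *temporal* call; p-values are corrected across terms by
Benjamini–Hochberg at q < 0.05 (method and alpha are parameters).
Direction is the sign of the derived-minus-ancestor mean share; the
temporal slope sign is the least-squares slope of the per-time genotype
difference on time. Terms with fewer than two loci are reported
untested. The sums of squares are computed in closed form for the
balanced design and cross-checked against a formula-interface OLS in
the suite. Deviation profiles report each term's six cell means centered
on their grand mean (exactly zero-sum by construction).

## Synthetic data

The generator emulates the *shape* of a duplicate two-genotype,
three-timepoint bulk RNA-seq contrast: ~28 GO-slim terms × 25 loci
(~700 mapped) plus ~9·10³ unmapped background loci, baseline FPKM drawn
log-normal (meanlog 2, sdlog 1.5 — conventional right-skew defaults,
not calibrated to any organism). Planted effects are specified in
**share units**, the units of the tested statistic, and mapped back
through the exact normalization inverse: a locus with baseline
v0 = log(x0 + 1) and target share q in a cell gets value 6·v0·q and
FPKM e^(6 v0 q) − 1, so a zero-noise pipeline recovers planted shares
exactly. A directional effect Δ moves derived cells +Δ/2 and ancestor
cells −Δ/2; a temporal slope s tilts the genotype difference by
s·(t − t̄) antisymmetrically. Per-replicate noise is additive on the
share scale (sd default 0.005), equivalent to log-normal multiplicative
noise on FPKM + 1. Fold-change loci are multiplied on the FPKM scale in
the derived genotype.

What the generator does **not** emulate: count-based mean–variance
coupling, library-size artifacts, correlated co-regulation within GO
terms, or annotation error. Passing recovery tests therefore
demonstrates correctness of the statistics under the stated noise
model, not performance on real sequencing data.

Named simulator fixtures encode qualitative regimes: `ancestor-like`
(onset deferred to T — zero fresh conidia in a cycle), `derived-like`
(early onset, ≥10⁷ conidia per 10 mL culture within one cycle, ≥100×
the ancestor-like pool), `near-extinction` (subcritical yield y ≈ 0.06;
a 100-propagule founding population dies within five daily transfers).

## Numerical and reproducibility choices

All stochastic operations take an explicit `numpy.random.Generator`;
identical seeds give bit-identical trajectories and matrices. The
brute-force onset grid and the Euler oracle use 10⁻³ h steps; share
identities are asserted to 10⁻¹²; the recovery and null-calibration
simulations use 10-term × 20-locus universes at 100–200 replicates —
sizes chosen so the properties under test (sensitivity ≥ 0.95 at
effect = 3× noise sd; family-wise false-flag rate within Monte-Carlo
error of the BH target) are measured with adequate precision at
desk-scale runtimes.

## Known limitations

- The life-history model freezes hyphal biomass at onset; no germination
  lag, death, or within-cycle resource depletion (the capacity cap acts
  only at the census level). A configurable growth lag was considered
  and deferred — it would rescale t_c without changing the optimum's
  structure.
- The simulator tracks genotypes, not cells; population sizes are
  expectations until the Poisson transfer draw.
- The per-locus share constraint makes a locus's six normalized values
  compositional (they sum to 1), which the per-GO ANOVA treats as
  ordinary responses; the null-calibration simulation confirms the BH
  target is respected under the generator's noise model.
- Real-data quantities tied to a specific genome annotation or database
  version (locus counts passing the filter, the number of significant
  GO groups, global F and R² values) are inherently data-dependent and
  are not reproduction targets.
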