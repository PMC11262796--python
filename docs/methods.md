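# Methods

## The model and the question

All computations operate on constraint-based metabolic models: a
stoichiometric matrix `S` (metabolites × reactions), flux bounds
`lb ≤ v ≤ ub`, and boolean gene–protein–reaction (GPR) rules.  The
steady-state assumption `S v = 0` plus the bounds defines a convex polytope
of feasible flux vectors.  Rather than optimizing a single objective (FBA),
the comparative workflow characterizes each model by the *uniform
distribution* over its polytope, sampled by MCMC, and asks which reactions'
flux distributions separate between two differently constrained models.
The readout of interest is a sign reversal: a reaction whose sampled median
is negative in one condition and non-negative in the other.

The package's shipped instance of that question is succinate dehydrogenase
(SDH, Complex II), which couples succinate ⇌ fumarate to the quinone pool
and can run in reverse under ischemia-like conditions, consuming the
electrons Complex I feeds into the quinone pool when the downstream
oxygen-dependent route (Complex III/IV) is restricted.

## Context-specific reconstruction

Presence calling thresholds an expression table per platform: a gene is
*absent* when its value falls below the cutoff in at least
⌈(n+1)/2⌉ of n replicates (the majority rule reduces to 2-of-3 at n = 3).
Defaults: transcript counts < 5, protein abundance < 2000.  Platforms are
merged conservatively — present on any platform wins; absent requires
absence on every platform where the gene was measured; genes measured
nowhere stay unmeasured.  GPR evaluation uses three-valued logic (AND =
complex subunits, OR = isozymes); a rule whose truth cannot be decided from
the calls evaluates *unknown* and is treated as active during pruning, so
reactions are never deleted on missing evidence.

Pruning visits the GPR-inactive reactions in lexicographic id order and
removes each only if the reduced model still passes the capacity check:
every protected function, witnessed by a named reaction (defaults on the
toy network: ATP synthase for ATP production, citrate synthase for the TCA
cycle, the lumped glycolysis step), must retain a feasible flux of at least
ε = 1e-6.  That ε sits three orders of magnitude above LP solver tolerance
(1e-9) and far below any meaningful flux on the ±1000 bound scale.  The
fixed visiting order makes pruning deterministic; an order-sensitivity
diagnostic reruns the procedure in reverse order and reports any reaction
whose fate differs (empty whenever the inactivated reactions do not
interact through the capacity guard).

## Comparative constraints

For a model pair (A, B) and two designated reactions — Complex I and the
oxygen transport step — the theoretical maximum `M` of each reaction is
computed by FBA on the *unconstrained* models, then bounds are set in
mirror image: A gets `CI.lb = f_hi·M_A(CI)` and `O2.ub = f_lo·M_A(O2)`;
B gets `CI.ub = f_lo·M_B(CI)` and `O2.lb = f_hi·M_B(O2)`.  Defaults
f_hi = 0.7 and f_lo = 0.3; the oxygen reaction uses the same fractions as
Complex I.  Construction fails loudly if either constrained model is
infeasible or if B's O2 lower bound does not strictly exceed A's O2 upper
bound (the intended ordering of oxygen intake).  Every maximum and bound is
appended to the model's provenance and surfaces in the pipeline run log,
since these are the pivotal intermediate numbers of the analysis.  A
sensitivity sweep utility evaluates the reversal call over a grid of
(f_hi, f_lo) pairs.

## Uniform flux sampling

The sampler parameterizes the polytope on the null space of `S`: FVA first
identifies coordinates pinned by conservation (range ≤ 1e-9), which are
fixed at their midpoint and excluded from the walk; a Chebyshev-style LP
(maximize the uniform box margin δ subject to `S v = 0`) provides a
strictly interior starting point.  In the null-space coordinates the chain
is hit-and-run: draw a direction, intersect the line with the box
constraints to get a chord, jump to a uniform point on it.  Hit-and-run
leaves the uniform law invariant for any symmetric non-degenerate direction
distribution, which licenses the *rounding* step: a short pilot run
estimates the sample covariance, and subsequent directions are drawn from
the fitted ellipsoid (Cholesky transform, geometric-mean normalized).
Rounding is what keeps mixing acceptable on elongated polytopes.

Defaults: 4 chains started from jittered points along random chords,
warmup 1000 steps/chain, thinning 10 × (polytope dimension), n = 5000 total
draws.  Randomness comes from a counter-based Philox generator, so a single
integer seed makes the output bit-identical across runs.  Every emitted row
is checked against `‖S v‖∞ ≤ 1e-6·max(1, ‖v‖∞)` and the bounds (±1e-6);
within a step, fluxes are clipped to the box to prevent float excursions at
chord endpoints.  Degenerate polytopes with no free directions return their
single point with a warning.

Convergence diagnostics compute split-chain R̂ (variance-ratio formula,
floored at 1.0 since sub-unit values are finite-sample noise) and an
effective sample size from pooled autocorrelations with initial-positive-
sequence truncation; constant (pinned) reactions are flagged not-applicable
rather than reported as NaN statistics.  The R̂ implementation is
cross-checked against ArviZ in the test suite.

## Shift detection

For every shared reaction the comparison computes medians and IQRs of both
sample sets, plus a histogram overlap coefficient: 50 shared bins spanning
the pooled 1st–99th percentile range (robust to single outlier draws),
overlap = Σ min(p_A, p_B) ∈ [0, 1], symmetric and invariant under common
affine rescaling.  A reaction is *shifted* when overlap < 0.2 **and** the
absolute median difference exceeds 1.0 × the pooled IQR; it is *reversed*
when additionally median_A < 0 ≤ median_B.  The thresholds are declared
package defaults (the underlying judgement is inherently visual) and are
exposed in the configuration.  No distributional test is applied to fluxes;
the two-threshold rule is deliberately conservative, and the control
comparison (two independent sampling runs of the same model) flags nothing
under it.

## Metabolomics indices

Because absolute abundances are not comparable across species, group
comparisons use *intra-sample* ratios — numerator/denominator within each
replicate, cancelling any per-sample scale factor — and the adenylate
indices: energy charge `(ATP + ½ADP)/(ATP + ADP + AMP)` (the standard
Atkinson definition, bounded in [0, 1] and equal to 1 iff ADP = AMP = 0),
AMP fraction, and ATP/ADP.  Group tests are unpaired two-sided Student's
(equal-variance) t-tests, on raw ratios by default with a log-transform
switch; Benjamini–Hochberg correction is applied per analysis family (all
ratios of a panel together; the three adenylate indices together).
Zero-variance degenerate comparisons produce NaN p-values and are excluded
from the BH family rather than propagated.  `pi_value_rank` computes
`LFC · (−log₁₀ p)` for rank-based downstream analyses and refuses p = 0
(callers floor tiny p-values explicitly).

## Synthetic data: what it emulates and what it does not

**Toy network** (24 reactions, 22 metabolites): glucose uptake and lumped
glycolysis, pyruvate dehydrogenase and carboxylase, a TCA loop whose SDH
step (`CII_toy`, bounds ±1000) is the only reversible TCA-cycle reaction,
an ETC (`CI_toy`, `CIII_toy`, `CIV_toy`) coupled through a proton-motive
pool to ATP synthase plus a proton leak, oxygen transport, an ATP demand,
and exchanges (glucose, oxygen, lactate, succinate, fumarate, water).  The
external fumarate supply (upper bound 60) is what gives the reverse-SDH
route enough capacity to absorb Complex I's quinol output when oxygen is
capped; without it the constrained bat-like model would be infeasible.
Every reaction carries a one-gene GPR (`<id>_g`).  Construction is verified
at build time: the model is feasible, passes the capacity check, and the
constrained pair admits negative `CII_toy` flux (FVA ≈ [−56, −48] in A vs
[2.3, 5.1] in B) — so the qualitative reversal is recoverable by design,
and the pipeline tests measure whether the sampler and comparison machinery
*find* it, not whether it exists.  The network makes no claim to
stoichiometric realism (no proton/charge balancing, no P/O ratios); it is a
test instrument.

**Expression generator**: negative-binomial counts (dispersion 10), three
replicates per platform, planted absent genes at mean 1 (transcript) /
500 (protein) versus present means 100 / 50000.  At these parameters an
absent gene falls below the transcript cutoff in all three replicates with
probability ≥ 0.95 and a present gene essentially never does, keeping the
planted truth recoverable at the stated thresholds.  No batch effects,
length bias or compositional effects are modeled — passing recovery tests
says the thresholding logic is correct, not that the thresholds are optimal
for real libraries.

**Metabolomics generator**: log-normal absolute abundances for a default
panel (TCA intermediates, pyruvate, lactate, adenylates), 3 + 3 samples in
two groups, with per-metabolite group fold-changes.  The noise decomposes
into a per-sample scale factor (σ = 0.1, shared by all metabolites of a
sample — cell-number and extraction variation) and a small per-metabolite
residual (σ = 0.03).  This mirrors real targeted-metabolomics data, where
intra-sample ratios of co-measured metabolites are far tighter than raw
abundances because the dominant noise is per-sample scaling that the ratio
cancels; it is also what makes planted ratio effects recoverable within 10%
at n = 3.  Default planted effects: succinate ×5.08 in the first group (so
the succinate/fumarate ratio is 5.44 there against a 1.07 baseline),
ATP ×0.4, ADP ×1.2, AMP ×3.0 (exactly a threefold-lower ATP/ADP and a
depressed energy charge), lactate ×0.5.

## Numerical choices

* LP: `scipy.optimize.linprog` (HiGHS) at its default primal/dual
  tolerances (~1e-9); LP status maps to optimal/infeasible/unbounded, and
  unbounded objectives are surfaced as missing-bound errors.
* Pinned-coordinate detection: FVA range ≤ 1e-9; sampler feasibility
  tolerance 1e-6.
* Default bounds for SBML files lacking them: ±1000 (reversible) or
  [0, 1000] (irreversible) — the COBRA convention.
* Ties and ordering: pruning order is lexicographic; reversed reactions are
  reported sorted by |median shift| descending; metabolite/reaction id
  matching is exact and case-sensitive.
* Degenerate inputs: zero-width polytopes return their single point with a
  warning; all-zero adenylate pools, zero ratio denominators and
  out-of-range p-values raise errors naming the offending sample/value.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the toy network (24
reactions, free polytope dimension ≈ 7) with 2000 draws per sampling run
and 10–20 replicate seeds, 5000 draws for the closed-form simplex moment
checks, 50 random networks for the vertex-enumeration LP oracle, and
100–1000 random vectors for the statistics oracles.  These sizes were
chosen so the whole battery completes in a few minutes on one CPU while
keeping every acceptance margin comfortably non-marginal.

## Known limitations

* No thermodynamic (loopless) constraints or enzyme-capacity modeling; a
  sampled flux distribution can include thermodynamically infeasible loop
  fluxes on networks that contain loops.
* The binary present/absent integration scheme ignores expression
  magnitude (no GIMME/iMAT-style continuous weighting) — by design, since
  the workflow being reproduced thresholds and prunes.
* Shift detection is threshold-based, not inferential; it answers "did the
  feasible flux distributions separate", not "is the difference
  statistically significant".
* The fbc gene-product reader uses gene-product ids as gene identifiers; an
  id↔label mismatch in an SBML file must be resolved upstream.
* The sampler is exact-uniform only asymptotically; diagnostics (R̂, ESS)
  are reported precisely so users can judge chain quality rather than
  trust defaults.
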