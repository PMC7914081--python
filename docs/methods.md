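# Methods

## Delay-logistic dynamics

The population model is the delay logistic equation

    dx/dt = mu * x(t - tau1) * (1 - x(t - tau2)/K)

with constant history x(t) = x0 for t <= 0 (an inoculation scenario).  mu
is the specific growth rate (1/h), K the carrying capacity, tau1 the
reproductive delay and tau2 the reaction delay (both hours).  With
tau1 = tau2 = 0 it reduces to the ordinary logistic equation, whose closed
form is the integrator's oracle.

**Integrator.**  Method of steps with fixed-step classical Runge–Kutta
(RK4); delayed lookups interpolate the already-resolved grid solution
linearly.  This is valid when `dt <= min(tau1, tau2)`; a delay shorter than
one step is handled by clamping the lookup to the newest resolved point (a
first-order approximation that keeps the identification objective smooth
near tau = 0).  The delay logistic can undershoot zero for large delays;
negative excursions are clamped to zero and reported once via a
`RuntimeWarning`, because abundances are non-negative.  |x| beyond 1e12
raises a divergence error naming the step.  Convergence is checked by
halving dt against the logistic closed form (the error at least halves).

Note that at mu = 0.5 the reference reaction delays of several taxa put
the equation in the oscillatory-unstable regime (mu*tau2 > pi/2): the
trajectory grows oscillations until it bounces off the non-negativity
clamp and settles into a sustained relaxation cycle.  Identification still
recovers the generating delays exactly on such trajectories (residual sum
of squares ~1e-13 at the truth), because the cycle shape is a sharp
function of the delays.

**Regime classifier.**  The deviation x - K over a trailing analysis
window (default the last half of the samples) is reduced to its
sign-change structure: no crossing -> asymptotic stabilization; crossings
with successive |peak| amplitudes shrinking by more than tol = 0.05 ->
convergent fluctuation; otherwise sustained/divergent.  Deviations below
1e-8*K are treated as zero so numerically converged oscillations do not
register spurious crossings.  The thresholds are explicit parameters.

**Growth-rate estimator.**  The discrete form mu = dx/(x dt), averaged over
a sample window (default whole series; the model constructor restricts it
to the early quasi-exponential phase x <= 0.2 K when estimating mu itself).

**Delay identification.**  mu and K are fixed externally (user-supplied or
estimated from the series: early-phase growth rate, trailing-half plateau
mean) rather than co-estimated — the 2-D (tau1, tau2) search is much
better conditioned.  The residual-sum-of-squares surface over the delay
box is rugged, so the optimiser is a 40x40 coarse grid scan followed by
Nelder–Mead refinement (xatol 1e-3 h), with the final point clipped to the
box and flagged if it sits at a bound.  95% intervals come from a residual
bootstrap: resample residuals with replacement, add to the fitted curve,
refit with Nelder–Mead started at the point estimate; 2.5/97.5 percentiles
over n_boot = 200 refits by default.  On noiseless self-generated data the
generating pair is recovered within the refinement tolerance across the
delay box (property-tested).

## The cellular automaton

State per site: occupancy, species identity, lag flag, lag timer.  The
lattice is a torus, so every site has exactly 8 Moore neighbours and 48
radius-3 move candidates.  One step applies three synchronous phases, each
drawing decisions from the state at the start of that phase:

1. **Lag induction.**  Every active occupied cell computes MLL, the count
   of opposite-role occupied Moore neighbours (vacant neighbours contribute
   nothing), and enters lag with its species' tier probability —
   collaborators alpha1/alpha2/alpha3 and scammers beta1/beta2/beta3 for
   MLL 6–8 / 3–5 / 0–2.  A config switch (`mll_mode="collaborator_sum"`)
   exposes the alternative reading in which MLL counts collaborator
   neighbours for both roles, for sensitivity checks; the default follows
   the feedback narrative (collaborators stall among scammers, scammers
   stall without collaborators).
2. **Lag bookkeeping and death.**  Lag timers advance; past the cap Lat*n
   the cell dies with probability p each step (the p-check precedes
   recovery); surviving lagged cells recover with probability 1/Lat
   (geometric, mean episode ~Lat steps — the model text gives no recovery
   schedule, and this choice makes both Lat and the Lat*n cap operative);
   recovered cells may re-enter lag later, with the timer reset.  Every
   occupied cell, lagged or not, then dies naturally with probability d.
3. **Proliferation.**  Vacancies are visited in uniformly random order;
   the occupied, non-lagged cells of the radius-3 shell volunteer
   independently with probability m; one volunteer is chosen uniformly and
   places an active offspring of its species in the vacancy.  A cell
   parents at most one offspring per step, newborns do not parent in the
   step of their birth, and lagged cells never parent (dormant cells do
   not divide).  Competition acts exclusively through lag induction,
   overrun death and space preemption; there is no additional explicit
   kill term.

Per-step counts of lag entries, recoveries, overrun deaths, natural deaths
and births are logged, and the occupancy identity
`occ(t+1) = occ(t) - deaths + births` is exact by construction and checked
in tests.  All randomness flows through one `numpy.random.Generator`, so a
seed reproduces every lattice bit for bit.  The vacancy-filling loop and
the DDE inner loop are numba-compiled; a pure-Python fallback gives
identical results.

## Community generation

A species is a vector [alpha1..3, beta1..3, m, p, d, Lat, n] drawn
uniformly and independently from fixed intervals: alpha tiers [0.7,1],
[0.3,0.7], [0,0.3]; beta tiers [0,0.3], [0.3,0.7], [0.7,1]; m [0,0.2];
p [0.8,1]; d [0.1,0.3]; Lat integer [6,10]; n integer [1,3].  The tier
intervals are disjoint up to shared endpoints, so the orderings
alpha1 > alpha2 > alpha3, beta1 < beta2 < beta3 and d < p hold almost
surely; ties at endpoints are broken by resampling the offending
coordinate, preserving uniformity on the constrained box.  Lat and n are
sampled as integers because they are step counts/factors.  One automaton
step nominally represents 1 h, making Lat in [6,10] commensurate with the
identified delays; nothing computes with this equivalence.

Defaults for the community scale are N = 20 species, collaborator fraction
N_p = 0.5 of species and M_p = 0.5 of cells (midpoints of their nominal
[0.4,0.6] and [0.3,0.7] ranges), target M = 10^4 cells per species, and a
100x100 lattice run for 1000 steps.  The nominal per-species populations
exceed any reasonable lattice, so M is a *target*: total occupancy is
proportionally rescaled to `max_fill` (default 0.5) of the lattice, the
budget split M_p : (1-M_p) between roles and equally among each role's
species.  Initial positions are uniform without replacement; all cells
start active.

**Colour.**  A species' display colour is a perceptually uniform colormap
(viridis) of the Euclidean norm of its vector divided by the norm of the
interval upper bounds ("magnitude mapped into [0,1]"; the norm is one
defensible reading of magnitude and is documented as such).  Colour is
never used in any analysis.

## Analyses

**Population series** count each species' occupied sites per snapshot
(lagged cells occupy sites and are counted).  **Simpson alpha** is the
Gini–Simpson index 1 - sum p_i^2 — chosen because high values are read as
high richness *and* evenness — with 1/sum p_i^2 available as a variant.

**Climax detection.**  A run is at climax when total occupancy varies by
less than 5% (relative) over the trailing 10% of steps; the climax
snapshot is the final one.  At reduced scale the final community can hold
fewer than 3 species, leaving a dendrogram undefined; the analysis then
walks back to the latest snapshot with at least 3 survivors and flags the
relaxation.  With 3 leaves the cophenetic coefficient is a correlation of
3 numbers and is accordingly unstable; treat it as qualitative at that
size.

**Clustering.**  Surviving species' vectors are min–max standardized to
[0,1] per coordinate using the fixed sampling intervals (probabilities and
step counts are otherwise incommensurable), then clustered for every
candidate (distance, linkage) pair — Minkowski r in {1,2} and Chebyshev
crossed with single/complete/average linkage, plus centroid linkage with
the Euclidean (Minkowski-2) distance only, since centroid merge heights
assume Euclidean geometry.  The cophenetic correlation between original
and tree-implied distances ranks the pairs; the maximum is flagged.  The
Minkowski exponent defaults to 2 and is exposed.  Trees export to Newick.

**Spatial aggregation.**  The statistic is the mean standardized-parameter
distance over all Moore-adjacent occupied pairs (each unordered pair
once); the null permutes species labels over the occupied sites, holding
the occupancy pattern fixed (199 permutations by default).  Negative
z-scores mean parameter-similar species sit together (patches).  A
single-species lattice has a degenerate null and is reported as such.

## What the synthetic generator does and does not emulate

Trajectory fixtures are exact delay-logistic solutions: they validate the
identification machinery (oracle recovery, bootstrap behaviour) but carry
none of the features of real 16S relative-abundance series —
compositionality, sampling noise, irregular sampling, shared-environment
correlations between taxa.  Passing the recovery tests therefore
demonstrates correctness of the estimator, not field performance.
Likewise the CA community is a caricature: two roles, uniform parameter
priors, no substrate field, no immigration.  Tests on it demonstrate the
model's internal mechanics, not oral-cavity dynamics.

## Scales used by the test suite

The comparison experiment runs 10 seeds of 100x100 / 20 species / 1000
steps in both conditions (~1 minute total); the climax cluster analysis
uses one 100x100 / 100-species / 1000-step run.  These sizes keep the
full suite around a minute while leaving the per-seed statistics
meaningful.

## Known limitations

* **Within-role exclusion is fast.**  Per-species natural death d in
  [0.1, 0.3] and move probability m in [0, 0.2] imply per-step selection
  coefficients of order 0.1 between species of the same role, so the best
  collaborator and the best scammer exclude their role-mates within a few
  hundred steps at any lattice size.  The delay-response feedback
  stabilises the two *roles* (the with-lag condition typically ends with
  one species per role, the no-lag condition with a single species); it
  does not neutralise fitness differences within a role.  Claims that most
  species coexist under these rules do not reproduce at this scale, and
  the package reports what it measures.
* Scammer-role persistence on a 100x100 torus is marginal: the role
  survives the initial dormancy-driven crash in roughly half of seeds.
  Larger lattices buffer this demographic fragility.
* The classifier's peak-ratio rule needs several resolved oscillations;
  very slowly damped responses near the stability boundary can be labelled
  sustained.
* Co-estimation of (mu, K, tau1, tau2) is deliberately not the default;
  fixing mu and K misspecifies the fit if the plateau is not representative
  of K.
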