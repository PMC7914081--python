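# oralca

Why does the oral cavity sustain a diverse microbial flora when only a
handful of substrates are available — an apparent violation of the
competitive exclusion principle?  `oralca` implements a mechanistic answer
built from two pieces:

1. **Delay-logistic population dynamics.**  Oral taxa accumulate
   intracellular energy stores and divide with a *reproductive delay*
   τ₁ and respond to density feedback with a *reaction delay* τ₂:

       dx/dt = μ · x(t − τ₁) · (1 − x(t − τ₂)/K)

   The package integrates this delay differential equation, classifies its
   response regimes (asymptotic stabilization → convergent fluctuation →
   sustained oscillation as the delays grow), estimates the specific growth
   rate μ = Δx/(xΔt) from abundance series, and identifies (τ₁, τ₂) from an
   observed series by dynamic response optimisation (least squares over a
   delay search box, with residual-bootstrap confidence intervals).

2. **A stochastic cellular automaton of community succession.**  Species are
   random parameter vectors [α₁..α₃, β₁..β₃, m, p, d, Lat, n] split into
   *collaborators* (decompose large organic matter into a shared
   small-molecule pool) and *scammers* (consume the pool without paying the
   cost).  On a periodic (torus) lattice with Moore neighbourhoods, each
   cell's chance of entering a dormant **lag phase** depends on how many
   opposite-role neighbours surround it — collaborators stall when crowded
   by scammers (α₁ > α₂ > α₃ across neighbour tiers 6–8 / 3–5 / 0–2),
   scammers stall when collaborators (their food source) are scarce
   (β₁ < β₂ < β₃).  This encodes the decomposition-product negative
   feedback without an explicit substrate field.  Lag episodes that overrun
   `Lat·n` steps expose the cell to death with probability `p`; every cell
   dies naturally with probability `d`; vacancies are filled by offspring
   of active cells in the 48-site radius-3 shell, each volunteering with
   its species' probability `m`.

On top of the simulator sit the community analyses: per-species population
series, Gini–Simpson α diversity dynamics, hierarchical clustering of the
climax community's parameter vectors with cophenetic-correlation model
selection, and a permutation z-score for the spatial aggregation of
parameter-similar species into patches.

The package is for quantitative microbial ecologists who want a tested,
reproducible implementation of this model family — to probe when delay
responses do and do not rescue coexistence, and to fit delay-logistic
models to their own abundance series.

## Worked example

Identify the delays of a synthetic *Haemophilus*-like series shipped by the
fixture generator (generated with τ₁ = 4.02 h, τ₂ = 8.53 h):

```bash
$ oralca fixtures --out fx
$ oralca identify-delays --series fx/series.csv --taxon Haemophilus \
      --mu 0.5 --carrying-capacity 1 --n-boot 50 --seed 1 --out haem.csv
Delay-logistic fit (dynamic response optimisation)
====================================================
observations        : 1001
mu (fixed)          : 0.5 1/h
K (fixed)           : 1
tau1 (reproductive) : 4.02 h  95% CI [4.02, 4.02]
tau2 (reaction)     : 8.53 h  95% CI [8.53, 8.53]
RSS                 : 6.48848e-13
bootstrap refits    : 50
```

The fit recovers the generating delays exactly (the series is noiseless, so
the residual bootstrap collapses onto the point estimate and the RSS is at
numerical zero).

Run the headline with/without-delay-responses experiment on a 100×100
torus with 20 species for 1000 steps:

```bash
$ oralca compare-delay --seed 3 --rows 100 --cols 100 --n-species 20 \
      --steps 1000 --stride 100 --out cmp
lag on : richness 2, late Simpson 0.313, multi-peaked species 0
lag off: richness 1, late Simpson 0.000, monotone species 20
```

With lag rules active the two ecological roles coexist (one surviving
species per role, late-window Simpson α ≈ 0.31); with lag probabilities
zeroed a single species excludes everything (Simpson α → 0).  Both runs
share the same species draw and initial lattice, so the difference is the
delay responses alone.  `oralca analyze --run cmp/lag_on` then clusters the
climax community and scores patch formation (`aggregation.json`,
`cluster_report.csv`, `dendrogram.png`).

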