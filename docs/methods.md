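# Methods

This note documents the models, conventions and design choices behind
`meadowdiv`, in the spirit of a statistical package's methods appendix.

## Data model and sampling units

The substrate is a sampling-unit × species matrix of non-negative integer
counts with a three-level metadata hierarchy (treatment / plot /
transect) and a species → trophic-guild table (phytophagous `Ph`,
predatory `Pr`, saprophagous `Sa`, omnivorous `Om`). Real-valued
abundances are rejected rather than rounded: a fractional count is
evidence of an upstream processing error, not data.

The default analytical unit is the **transect** (48 units in the
emulated design), preserving within-plot variation; dark diversity is
evaluated at **plot** level by default because Beals smoothing needs the
co-occurrence context of a whole plot. Both choices are configuration
options and are recorded in the run manifest. Aggregation sums counts
within groups and conserves the grand total at every level.

## Alpha diversity

Four indices per unit × guild, all with natural logarithms:
`MR = (S − 1)/ln N`, `H = −Σ pᵢ ln pᵢ`, `J = H/ln S`, `D = 1 − Σ pᵢ²`,
where proportions run over positive counts only (`0·ln 0 := 0`).
Degenerate conventions: a monoculture has `MR = 0` (also for `N = 1`, the
limit convention) and `J = 0` (the 0/0 case; a monoculture has no
evenness to measure, and a finite value keeps guild tables dense).
Unit × guild cells with zero individuals are *missing*, not zero — an
absent guild is not an observation of zero diversity. Min–max
normalization for cross-index display maps a constant vector to 0.5.

## Zeta diversity

The expectation of the shared-species count over all `C(n, i)` unit
combinations has the exact closed form `ζᵢ = Σₛ C(oₛ, i)/C(n, i)` in the
per-species occupancies `oₛ`; monotone nonincrease in `i` follows from
the hypergeometric ratio and is asserted in tests rather than re-proved
at run time. Per-order dispersion (sd across combinations) is enumerated
exactly while the number of combinations is at most 100,000 and otherwise
estimated from 10,000 sampled combinations; the expectation itself never
relies on sampling in exact mode. A Monte-Carlo mode (uniform
combinations, units without replacement within a draw, mandatory seed)
exists for very large unit counts.

Consecutive ratios `ζᵢ₊₁/ζᵢ` are reported as missing (NaN) once
`ζᵢ = 0`: a curve that has dropped to zero has no retention probability
left to measure, and propagating 0/0 would fabricate structure. The
default maximum order is `min(10, n)` — high enough to cover the orders
at which widespread/rare contrasts play out, never beyond the stratum's
unit count. No parametric (exponential vs power-law) fit of the decline
curve is attempted; curve shape is interpreted qualitatively.

The permutation test compares two strata by pooling their units,
reassigning them at random with group sizes preserved, and using
|ζ_A(i) − ζ_B(i)| per order plus the maximum over orders as the global
statistic, with add-one p-values `(1 + #{null ≥ obs})/(n_perm + 1)`.
This is one defensible operationalisation of "significance of a zeta
contrast"; order-wise p-values are reported alongside the global one so
users can see where the curves differ.

## Dark diversity

Beals smoothing estimates the probability of species `j` at unit `k`
from the other species present there:
`P_kj = (1/S′ₖ) Σ_{i ∈ k, i≠j} M_ij/n_i`, with the species' own
presence at `k` excluded (self-exclusion is verified in tests by a
perturbation argument). The reference pool supplying `M_ij` and `n_i`
defaults to the full dataset across treatments — the pooled estimate
stabilises co-occurrence frequencies for rare species — with a
per-treatment option for strictly local pools.

Per-species dark thresholds are a low quantile (default `q = 0.01`,
linear interpolation; `q = 0` gives the strict minimum) of the species'
Beals values at the units where it is present. Membership is strict
(`P > threshold`) so a species sitting exactly at its presence minimum
is not flagged. Species with no occurrences, or occurring in every unit
(no absences to classify), are skipped and reported. Dark sets shrink
monotonically as `q` rises.

Summaries: `PDD = ND/NP` counts units (not pooled treatment-level
occurrences) in both numerator and denominator, with `NP` = units where
the species is present or dark; `CCI = SR/(SR + PR)` per unit, NaN when
both are zero (an empty stratum is not a complete one). Binarisation of
counts is the outlier-elimination step: a single stray individual
registers identically to a resident population at the incidence level,
which is the level at which both zeta and Beals operate.

## Treatment comparison

Each response is gated by per-group Shapiro–Wilk and a median-centered
(Brown–Forsythe) Levene test, both at level 0.05 (configurable). All
pass → one-way ANOVA with Tukey HSD; any failure → Kruskal–Wallis with
Dunn's test, Holm-adjusted (Bonferroni or none available). A group with
zero variance or fewer than three observations cannot be assessed by
Shapiro–Wilk and conservatively forces the nonparametric route, with a
note in the result. Omnibus statistics delegate to scipy; Dunn's test
(pooled mean ranks, tie-corrected variance) and the insert-and-absorb
compact letter display are implemented here. The letter display is
consistent with its pairwise matrix by construction: a split only ever
separates the significant pair, so non-significant pairs always retain a
shared letter.

Under the null the full gated cascade rejects at very close to the
nominal 5% (both routes are valid null tests, so gating does not distort
level); this calibration is exercised over 2,000 simulated datasets of
4 groups × 12 observations in the acceptance checks.

## Synthetic communities

The generator emulates the nested design (4 treatments × 3 plots ×
4 transects, 88 species) without imitating any real species identities.
Guild membership follows a largest-remainder allocation of the guild
fractions (default 40/25/20/15% for Ph/Pr/Sa/Om, a typical
phytophage-dominated grassland sweep-net community). Each treatment has
an occupancy profile drawn per species from a Beta law —
widespread-dominated `Beta(5, 2)`, rare-dominated `Beta(1, 6)`, mixed
`Beta(2, 2)` — a one-knob control of the widespread/rare spectrum. The
default profile map (FE, FR widespread-dominated; GC, CK rare-dominated)
mirrors a restoration gradient in which exclusion fencing and no-till
reseeding stabilise widespread species while planted monocultures and
grazing drive rare-species turnover.

Presence at a unit is Bernoulli in the species' occupancy probability;
abundance conditional on presence is zero-truncated negative binomial
(mean 6, dispersion 0.8), chosen so a default community carries roughly
10–15 thousand individuals. Presence and abundance are deliberately
decoupled: zeta and dark diversity are incidence-based, so only the
alpha indices see the count law, and the count law is a stand-in — no
claim is made that real sweep-net abundances are negative binomial.

Planted dark diversity: after generation, each occurrence of a *suitable*
species (occupancy probability ≥ 0.5, the operational species-pool
membership rule) is deleted with probability 0.1 and recorded. Recovery
scoring compares the flag rate on withheld pairs against the flag rate
on absences of never-suitable species — the chance baseline.

One seed sequence drives everything; per-treatment sub-streams are
spawned deterministically so a treatment's draws do not depend on the
parameters of the others. Same seed ⇒ bit-identical matrix and truth.

**What the generator does not emulate:** spatial autocorrelation within
plots, dispersal limitation, temporal dynamics, detection error in
sweep-netting, and abundance-dependent detectability. Passing tests
therefore demonstrate that the machinery recovers structure *of the kind
the generator plants*; they do not certify recovery rates on field data,
where species pools are not defined by a latent threshold.

## Pipeline and reproducibility

`run_pipeline` executes composition → alpha → zeta → dark → comparison
from one config and writes a CSV/JSON bundle plus a manifest echoing the
config, seed and analysis decisions (quantile, reference scope, unit
levels). Outputs are byte-identical across reruns of the same config and
seed; shares in the composition table are rounded half-up to two
decimals, CSV floats use `%.10g` with `.` decimals and no thousands
separators. A stage failure aborts the run with the stage named and
removes partial outputs.

Problem sizes in the validation suite — 1,000 random matrices (≤8 units,
≤15 species) for the zeta enumeration oracle, 200 for the Beals
double-loop oracle, 20 simulated studies for dark recovery, 100 paired
simulations for profile discrimination, 2,000 null datasets for
calibration — were chosen as the smallest scales at which each property
is statistically unambiguous.
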