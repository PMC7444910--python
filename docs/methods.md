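# Methods

## Model and mean-field representation

A cell-fate model is a continuous-time multi-type branching process over
states `X_1..X_m` with division (`lambda_i`, daughter-pair distribution
`r_i{j,k}`), direct state change (`omega_ij`) and loss (`gamma_i`). All
rates are constant non-negative reals in an implicit, consistent time unit:
cell-extrinsic (density-dependent) regulation and spatial arrangement are
out of scope, which is adequate for long-term clonal statistics in two- and
three-dimensional tissues.

Daughter pairs are stored unordered with canonical index order `j <= k`;
ordered outcomes are recovered by splitting the probability evenly between
the two orderings. This removes a redundant degree of freedom and is
consistent with the symmetrised per-daughter probability
`r_i^j = sum_k (r_ijk + r_ikj)/2` used by the mean field. The mean cell
numbers obey `d n̄/dt = A n̄` with `A[j,i] = kappa_ij` off the diagonal and
`A[i,i] = kappa_ii - delta_i`, where `kappa_ij = 2 lambda_i r_i^j +
omega_ij` and `delta_i = lambda_i + sum_j omega_ij + gamma_i`. Two exact
identities are used as validation everywhere: column `i` of `A` sums to
`lambda_i - gamma_i`, and `A` has no negative off-diagonal entry
(cooperativity), which by Perron–Frobenius gives each irreducible block a
real dominant eigenvalue.

## Homeostasis, compartments, classification

The cell-state network has an edge `i -> j` wherever `kappa_ij > 0`. The
network is condensed into SCCs (networkx); per-SCC dominant eigenvalues are
taken from a full eigen-decomposition of the principal submatrix of `A`
(models here have m ≤ ~20, so no iterative eigensolver is needed). The
model is **homeostatic** iff the condensation has a unique source SCC (the
apex) with `|mu| <= 1e-8` while every other SCC has `mu < -1e-8`. The
tolerance separates generator-tuned zeros (machine-precision) from
genuinely negative roots. Models with multiple source SCCs are rejected for
clonal analysis: clones are induced from one renewing cell, so one lineage
apex is assumed throughout.

The apex SCC is the renewing compartment R, the rest is committed, C.
Classification is event-by-event: **GIA** iff no R-state has positive loss
or a transition into C, and every positive-probability division of an
R-state has exactly one R daughter; otherwise **GPA**. (C-state divisions
cannot produce R daughters without merging the SCCs, so no separate check
is needed.)

Effective compartment rates weight per-state rates by stationary occupancy
`P_i^R = n̄*_i / sum_{j in R} n̄*_j` (and analogously over C):
`lambda_R = sum_R lambda_i P_i^R`, `gamma_C = sum_C gamma_i P_i^C`,
`omega_RC = sum_{i in R, j in C} omega_ij P_i^R`, and `r_RR` (`r_CC`) are
division-rate-weighted probabilities of two-R (two-C) daughter pairs — the
frequency-consistent choice for rates defined as mean event frequencies.
Summing the stationary equations over R-rows gives the exact balance
`lambda_R r_RR = lambda_R r_CC + omega_RC + gamma_R`; the textbook form
without `gamma_R` corresponds to routing direct R losses through a
short-lived committed state, and the generator never assigns R losses, so
both forms coincide on everything generated here. For heterogeneous C
compartments, `lambda_C` is reported as the occupancy-weighted mean
division rate only. The stationary vector is the SVD null vector of `A`,
sign-fixed, verified non-negative with residual below 1e-9, and normalised
so the R compartment sums to one. In the dynamic-heterogeneity model the
switching rate written `omega_S` is the D→S rate and `omega_D` the S→D
rate; this is the direction convention under which the stated balance
`gamma/lambda = omega_S/omega_D` produces a zero apex eigenvalue.

## Random model generation

The generator is this package's own design. For a **GPA** target it samples
an apex topology (a transition cycle through `n_R` renewing states plus
density-controlled extra edges), division outcomes per renewing state with
symmetric-renewal probability strictly above symmetric-commitment
probability (so the untuned apex eigenvalue is positive — both are drawn
uniformly, commitment from U(0.05, 0.25) and the renewal excess from
U(0.1, 0.5)), a committed DAG whose per-state loss rate is its division
rate plus its forward transition outflow plus U(rate range) (making every
committed block strictly subcritical), and all remaining rates i.i.d.
U(0.1, 1) by default. Each renewing state receives one transition into C
whose rate carries a common multiplier `theta`; the apex eigenvalue is
continuous and strictly decreasing in `theta` (a positive diagonal
perturbation of an irreducible Metzler block), so a bracketed Brent solve
drives it to zero at machine precision. For a **GIA** target every renewing
division is constructed with exactly one renewing daughter, which zeroes
the apex column sums and hence the apex eigenvalue identically; only the
committed side needs loss rates above division rates, with no tuning.
`rescale_renewing` multiplies every rate attached to R-states by a factor
`c`; this scales the whole apex block of `A` (eigenvalue stays zero) and
scales `lambda_hat_R = lambda_R/gamma_C` exactly by `c`, which is how
campaigns reach the fast-renewal regime `lambda_hat_R = 30`.

One integer seed drives named RNG streams (topology, rates, per-clone
simulation, pilot ensembles) via numpy `SeedSequence`, so models, ensembles
and whole campaigns are bit-reproducible.

## Simulation

Clones are simulated with the direct-method Gillespie algorithm — exact
waiting times and propensity-proportional event choice; no tau-leaping,
because the claims under test are distribution-level. The kernel recomputes
the total propensity exactly at every event (incremental updates drift),
resolves boundary draws toward positive-rate channels, and uses an inlined
xorshift128+ generator so the numba-compiled and pure-Python paths are
bit-identical. Counts are recorded on a fixed checkpoint grid (default 50
log-spaced times ending at `t_max`) rather than as event logs; extinction
is absorbing and the extinction time is recorded exactly. Populations above
`max_cells = 1e6` raise an error (runaway, i.e. non-homeostatic input)
rather than truncating silently.

Stopping rules: `fixed_time` uses the given horizon; `gia_default` uses
`t_max = 20/alpha_min`, where `alpha_min` is the smallest strictly positive
process rate (zero rates denote absent processes); `gpa_default` takes the
time at which a 2000-clone pilot ensemble (own RNG stream) first reaches
98% extinction, read off the order statistics of exact extinction times,
with a doubling horizon until enough clones have died. Survivor flags are
evaluated per checkpoint; all clone-size statistics are conditioned on
survival (`n > 0`), and extinct clones enter only the extinct-fraction
curve.

## Reference laws and oracle

The two-state GIA chain (conserved `X1` feeding `X2` with immigration
`lambda_1`, birth `lambda_2 n`, death `gamma n`, `lambda_2 < gamma`) has
the negative-binomial stationary law (shape `lambda_1/lambda_2`, success
`lambda_2/gamma`; Poisson of mean `lambda_1/gamma` at `lambda_2 = 0`) with
mean `lambda_1/(gamma - lambda_2)`. The closed-form rescaled density is
evaluated entirely in log-space (log-Gamma differences; the direct Gamma
form overflows beyond `lhat1 ~ 170`), with the `lhat2 -> 0` branch defined
by continuity as the continuised Poisson law. The closed form is asymptotic
in the stationary mean: it integrates to 1 within 1e-12 once the mean is
≳ 40 but carries an O(1e-4) normalisation defect at mean 10, which the
tests document explicitly. Its variance is exactly `1/lhat1`, matching the
Normal(1, 1/lhat1) fast-division limit.

A brute-force oracle integrates the master equation of small models
(m ≤ 3) on a truncated lattice with an absorbing overflow state; caps
double until the overflow mass at the evaluation time is below 1e-8, and
the linear propagation uses sparse `expm_multiply`. The oracle is kept
independent of the simulator and of the closed forms, and the three are
cross-checked pairwise in the tests.

Distribution agreement is measured by the two-sided KS distance — for
discrete laws the sup is taken over the integer support. Bimodality (for
the two-renewing-state test case with slow switching and unequal division
rates) is detected by counting well-separated modes of a Gaussian KDE with
a valley-depth rule; at the fixture's peak separation (committed means 30
vs 90 with Poisson-scale widths) this is an unambiguous discriminator.

## Desk-scale campaign conditions

Campaigns default to 20 random models per class with m ∈ [3, 6] states.
GPA ensembles use 50,000 clones per model: at the 98%-extinction stopping
time only ~2% of clones survive, and ~1000 survivors are needed for the KS
statistic to resolve the 0.08 acceptance band (the null's 99.9th percentile
at n = 1000 is ≈ 0.06). GIA ensembles use 2000 clones (no extinction, every
clone survives). Models whose final surviving mean is below two are
excluded from ensemble summaries. Cross-model envelopes are pointwise 5/50/95
percentiles of the per-model ECDFs on a common grid.

## What the generator emulates — and what passing tests do not show

Random models emulate homeostatic renewal hierarchies with a single lineage
apex, Markovian constant rates, and no spatial structure or feedback. Real
tissues violate several of these (short-time non-Markovian effects, niche
regulation, one-dimensional arrangements such as crypts or tubules), so
passing tests establish the internal consistency of the theory and the
exactness of the simulator, not the realism of any particular tissue model.
Known limitations worth stating: at the 98%-extinction time, GPA models with
slowly clearing committed compartments still carry a small excess of
lingering committed-only clones (the deviation decays as the horizon
grows); the Normal limit for GIA requires all renewing
rates, not just divisions, to be fast relative to `gamma_C` — slow internal
R-switching with unequal division rates instead yields bimodal clone sizes;
and the closed-form rescaled law is reliable only for stationary means
above a few tens.
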