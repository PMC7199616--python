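# Methods

## Model summary

The package implements a scale-relativistic ("fractal space") model of
lipoprotein state dynamics in one spatial dimension.  Its ingredients, in
the order the code builds them:

1. **Fractal increments.**  The nondifferentiable part of the coordinate
   differential satisfies `dξ = λ^(1/2)-type` scaling with
   `⟨dξ⟩ = 0` and `⟨dξ²⟩ = 2λ·dt^(2/D_F)` in the isotropic Markov case.
   The model text associates the fractalization with "Lévy-type" motion
   while simultaneously assuming a finite covariance; these are
   incompatible for genuinely heavy-tailed laws.  The increments are
   therefore realized as **Gaussians** — the unique stable law with finite
   variance — which keeps every moment-based test sharp.  This is a
   documented modelling choice, not a resolution of the tension.

2. **Scale-covariant derivative.**  `d̂/dt = ∂t + V·∂z − iD·∂zz` with
   `D = λ·dt^(2/D_F−1)`.  The anisotropic constant-tensor variant
   (coefficients `(d, d̄)`, complex combination `d − i·d̄`) is available via
   an optional argument; the isotropic case corresponds to `(0, 4λ)`.

3. **Effective constants.**  All solvers consume only
   `D`, `ħ_eff = 2m₀D` and `μ = 2m₀D² = ħ_eff²/(2m₀)`.  Either the
   microscopic quadruple `(m₀, λ, dt, D_F)` or the pair `(μ, ħ_eff)` may be
   supplied; `D = μ/ħ_eff` closes the triple.

4. **Stationary eigenproblem.**  `−μθ'' + Uθ = Eθ` on `[−l, l]` with hard
   walls and a square barrier `V₀` on `|z| < d`.  Value/derivative matching
   at `±d` forces the interior coefficient ratio to `ρ² = 1`, splitting the
   spectrum into symmetric (`cosh`) and antisymmetric (`sinh`) families.

5. **Dynamics.**  `i·ħ_eff·∂tψ = −μ∂zzψ + Uψ`, with density/current
   `ρ = |ψ|²`, `J = iD(ψ∂zψ̄ − ψ̄∂zψ)` and the conservation law
   `∂tρ + ∂zJ = 0`.

## Secular equations: the k/q form

Dividing the value-matching equation by the derivative-matching equation at
each interface and eliminating the interior ratio yields

    tan(k(l−d)) = −(k/q)·coth(qd)   (symmetric)
    tan(k(l−d)) = −(k/q)·tanh(qd)   (antisymmetric).

Only the `k/q` prefactor reproduces the hard-wall limit `k(l−d) → π` as
`V₀ → ∞` and agrees with the independent finite-difference diagonalization;
an alternative `q/k` reading of the prefactor fails both checks and is not
used.

**Pole-free residuals.**  The tan/coth forms have poles that defeat naive
bracketing.  The implemented residuals clear denominators and additionally
normalize by `cosh(qd)`:

    F_sym(E)  = q·tanh(qd)·sin(k(l−d)) + k·cos(k(l−d))
    F_anti(E) = q·sin(k(l−d)) + k·tanh(qd)·cos(k(l−d)).

These share roots and signs with the cleared-denominator forms but stay
bounded for arbitrarily large `q·d` (the unnormalized `sinh`/`cosh` forms
overflow beyond `q·d ≈ 350`, which the `V₀ = 10⁶` decoupling studies would
hit).  At `d = 0` they reduce to the barrierless-box conditions
`k·cos(kl)` and `q·sin(kl)`.

**Root finding.**  Roots are asymptotically uniform in `k` (spacing
`≈ π/(l−d)`), so the bracketing scan is uniform in `k` with at least 8
points per oscillation (400-point floor); a uniform-in-`E` scan aliases
higher wells when `V₀` is large.  Each bracket is polished by Brent's
method at `rtol ≈ 4·eps`.  Energies at or above `V₀` are rejected with a
typed error: the construction assumes an evanescent interior.

**State assembly.**  With `A = 1`, the `z = −d` matching pair gives
`B·e^(−qd) = (s + (k/q)c)/2`, `C·e^(qd) = (s − (k/q)c)/2`
(`s = sin k(l−d)`, `c = cos k(l−d)`), and parity fixes `D = ∓A`.  All four
matching equations must close to 1e−9 relative or the energy is rejected.
The interior is *evaluated* through the parity-stable `cosh(qz)/cosh(qd)`
and `sinh(qz)/sinh(qd)` ratios (written with scaled exponentials), which
remain finite where the raw `B e^(qz) + C e^(−qz)` amplitudes would
overflow.  Normalization is analytic (piecewise closed-form integrals);
the sign convention — absent from the model itself — is positive at the
right-well midpoint `z = (d+l)/2`.

**Reference level.**  The "unsplit fundamental level" is not pinned by a
formula in the model; it is implemented as the barrierless-box ground
energy `E₀ = μ(π/2l)²` and exposed as a labelled field (`E0_ref`, with
`q₀ = √((V₀−E₀)/μ)`) so an alternative convention can be substituted.
The doublet non-degeneracy factor is `coth(q₀d)/tanh(q₀d) = coth²(q₀d)`,
strictly above 1 for `q₀d > 0` and decreasing to 1 as the wells decouple;
in double precision `tanh` saturates to 1.0 near `q₀d ≈ 19`, which bounds
the numerically resolvable range.

## Finite-difference oracle

An independent check shares no code with the secular path: the standard
three-point discretization of `−μθ'' + Uθ` on `n` interior points
(Dirichlet walls by omission), diagonalized as a symmetric tridiagonal
matrix (LAPACK, lowest states only).  The barrier enters via its **exact
cell average** over `[z_i − h/2, z_i + h/2]`, which removes the O(h)
interface error of vertex sampling for any interface position and reduces
to the symmetric `V₀/2` rule when a grid point sits exactly on `±d`.  The
leading error is then cleanly O(h²) and Richardson extrapolation (with the
actual mesh ratio, since `h = 2l/(n+1)` makes integer grid ratios
non-dyadic in `h`) yields reference eigenvalues good to ~1e−10 relative at
the 2000/4000 grids used in the tests.  Parity is assigned from the
overlap of each eigenvector with its reversal; a doublet that is
degenerate at machine precision legitimately mixes parities, in which case
the state is labelled `unknown` and energy comparison proceeds on sorted
values.

## Time propagation

One-step trapezoidal (Cayley) integration
`(1 + iΔtH/2ħ)ψⁿ⁺¹ = (1 − iΔtH/2ħ)ψⁿ` with the same tridiagonal `H` as
the oracle.  The scheme conserves the discrete L² norm identically in
exact arithmetic; the *contract* is the observed norm drift (≤ 1e−10 over
a run), not the scheme name.  Grids of ~1200 points and steps with
`E·Δt/ħ_eff ≲ 0.05` keep the measured tunneling period within 2% of
`2π·ħ_eff/ΔE` at a cost of ~1 s per run.

**Velocity and geodesic residual.**  Logarithmic-derivative velocities
mask points within 10 machine epsilons of a node (a field with > 20% of
interior points masked is rejected).  The geodesic residual of an
eigenstate velocity cancels analytically piecewise (for `u = θ'/θ` with
piecewise-constant `U`: `u' = −(E−U)/μ − u²`, hence `2uu' + u'' = 0`), and
converges at O(h²) numerically — *outside* (i) a 3-point buffer around the
interfaces `±d`, where `u'` jumps, and (ii) a wall layer (default 5% of
the domain per side), where `u ~ 1/(z∓l)` diverges and centered stencils
amplify as `h⁻³`.  Both exclusions are structural features of hard-wall
log-derivatives, not tuning knobs.

## Synthetic data and fixtures

The seeded fixture generator emulates the study conditions: `l ∈ [1, 5]`,
`d/l ∈ [0.05, 0.8]`, `V₀·l²/μ ∈ [5, 500]`, `D_F ∈ {1.5, 2, 2.5, 3}`.  The
scale family is realized as `(m₀ = 0.5, λ = 1, dt = 1, D_F)`: `dt = 1`
makes `D = λ` for every `D_F`, so all fixtures share `μ = ħ_eff = 1` and
the `V₀` window applies directly.  Candidates without a sub-barrier
doublet (narrow wells under a low barrier) or with a numerically
degenerate one are resampled deterministically.  What the generator does
*not* emulate: real lipoprotein kinetics carry no published calibration of
`(λ, dt, D_F, l, d, V₀)`, so passing tests demonstrate the internal
consistency of the model and solvers, not agreement with measured
LDL/HDL conversion rates.

## Monte-Carlo and estimation choices

Increment ensembles are seeded (`numpy` Generator, one integer seed per
ensemble; default 0).  `D_F` is recovered as `2/slope` of the least-squares
fit of `log⟨dξ²⟩` vs `log dt`; recovery within 5% uses 10⁴ paths over 8
resolutions spanning a decade.  Moment checks use 3-standard-error bands
(`SE(mean) = σ/√n`, `SE(s²) ≈ σ²√(2/(n−1))`).

## Problem sizes

Default test and reproduction runs use: 10⁴–10⁵ Monte-Carlo paths, 400+
point secular scans, 500–4000-point finite-difference grids (20 seeded
geometries for the oracle-equivalence property), ~1200-point propagation
grids with 2000–5000 steps.  These sizes put every verification at least
an order of magnitude inside its tolerance while keeping the full suite
around a few seconds.

## Known limitations

- One spatial dimension only; square wells only (a parabolic-well variant
  of the potential is mentioned in the model's narrative but comes with no
  parameters and is out of scope).
- Only the lowest doublet is modelled; above-barrier and higher states are
  rejected rather than solved.
- Gaussian realization of the increment law (see above); no heavy-tailed
  simulation, no 3-D increments, no empirical multifractal spectrum
  estimation.
- `ρ² = 1` root extraction conditions like `exp(2qd)`: beyond `q·d ≈ 18`
  the consistency function is numerically flat around its roots.
- No quantitative calibration to clinical lipoprotein data exists; the
  package's claims are structural (orderings, identities, conservation
  laws, limits), and its tests verify exactly those.
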