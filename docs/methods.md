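# Methods

## Model and assumptions

The filament is slender, inextensible, headless and planar, immersed in
Stokes flow with resistive-force-theory drag (coefficients `c_perp`,
`c_par` per unit length). Internal activity enters as a distributed moment
`m(s, t)`; the filament is force- and moment-free at both ends. All
quantities are dimensionless: lengths scaled by the filament length `L`,
time by the inverse angular frequency `1/omega`, moments by `A/L` with `A`
the bending modulus. The single control parameter is the sperm number
`Sp = L (omega c_perp / A)^{1/4}`, the filament length in units of the
elastic penetration length.

The solver works at leading order in the forcing amplitude `epsilon`. The
tangent-angle dynamics linearize to the hyperdiffusion equation
`Sp^4 Psi_t + Psi_ssss = m`, where `Psi` is the thrice-integrated tangent
angle; the force/moment-free ends become `Psi_t = Psi_st = 0` there. For a
single-frequency forcing `m = Re[f e^{-i phi} e^{it}]` the ansatz
`Psi = Re[Phi e^{it}]` is exact and the problem reduces to the complex
two-point boundary-value problem for `Phi` quoted in the README. Tension
does not enter at this order; the time-averaged global torque vanishes
identically (verified numerically at every sampled time in the tests). The
leading-order swimming speed appears at `O(epsilon^2)`; the package reports
the *reduced* speed `U`, which strips the drag-anisotropy prefactor
`(c_perp - c_par)/(2 c_par)`. `actifil.dimensional.redimensionalize`
restores laboratory units.

## Green's function

`G(s; xi)` satisfies `Sp^4 i G + G'''' = delta(s - xi)` with clamped-form
ends. Rather than transcribing a closed form, each side of the source is
expanded in the four natural modes `e^{k s}`, `k = Sp eta i^j` with
`eta = e^{-i pi/8}`, and the eight coefficients are found from an 8x8
linear system: four boundary conditions, continuity of `G, G', G''` at
`s = xi`, and the unit jump `G'''(xi+) - G'''(xi-) = +1` (obtained by
integrating the defining equation across the delta; order-3 evaluation at
`s = xi` returns the right-side limit). Growing exponentials are anchored
at the far end of their sub-interval (`e^{k(s - xi)}` or `e^{k(s - 1)}`),
which keeps the system's condition number at a few hundred for all
`Sp <= 30`; the constructor measures the condition number and refuses
anything above 1e12. Coefficients are solved in a batch per source-point
array; evaluation deduplicates repeated sources.

An independent second-order finite-difference solver
(`actifil.oracle.bvp_oracle`, five-point biharmonic stencil with ghost-node
clamped ends) provides the verification path; it is never used in the main
pipeline.

## Speed kernel and its discretization

The first-argument derivative `G'(xi1; xi2)` yields the symmetric and
antisymmetric parts

    Gs = -1/2 (Im G'(xi1;xi2) + Im G'(xi2;xi1)),
    Ga = -1/2 (Re G'(xi1;xi2) - Re G'(xi2;xi1)),

and `Gswim = Gs cos(phi1 - phi2) + Ga sin(phi1 - phi2)`. The kernel is
sampled on `N` midpoint nodes `(2n-1)/(2N)` (default `N = 100`; the modal
results are insensitive to `N` well before that) and symmetrized to remove
floating-point asymmetry. Continuous-profile speeds use the midpoint rule
`U = f^T Gswim f / N^2`; point actuators are never smeared onto the grid —
the kernel is evaluated analytically at the actuator coordinates, which is
exact for delta forcing.

Two independent routes to `U` exist: the kernel bilinear form and the
time-average `U = -2 int <Psi_sss Psi_sst> ds` computed from the
reconstructed motion. Their agreement on seeded random profiles is the
package's central correctness test. Numerical choices for that comparison:
time averaging uses 256 uniform samples over one period (exact for
trigonometric signals); shape amplitudes are integrated with 40-node
Gauss-Legendre panels split at `xi = s` (where `G'''` jumps) and at any
discontinuity of a piecewise profile; the `s` integration uses Simpson's
rule on 801 points. The midpoint kernel route converges at `O(1/N^2)`, so
cross-route tests run it at `N = 200`-`400` (or Richardson-extrapolate the
`N = 100/400` pair when a 1e-5 comparison against the analytic four-mode
speed is wanted); profiles with strong cancellation (`|U|` a few orders
below its uncancelled scale) are the reason the default `N = 100` is not
enough for those comparisons, while being fully adequate for eigenvalues
and design optima.

## Modal basis

The sampled kernel is symmetrized, eigen-solved with a symmetric solver,
and eigenvalues divided by `N`. Modes are ordered by decreasing magnitude;
within the numerically exact +- reflection pairs the positive member is
listed first. Eigenfunctions are normalized to unit mean square
(`sum g^2/N = 1`) with the largest-magnitude sample made positive (ties to
the smaller index). The travelling-wave scan re-phases the `Sp`-dependent
`Gs`, `Ga` once per `Sp` for every wavenumber `k`, covering by default
`Sp` in [0.05, 6] (step 0.05) and `k` in [-3, 3] (step 0.02). Behaviour
below `Sp = 0.05` is numerically delicate and not certified; the scan
optimum pushes toward small `Sp` with an essentially flat ridge.

## Analytic monophasic eigensystem

For `phi = 0` an eigenfunction with non-zero eigenvalue must satisfy
`lambda f = Re[I3]` where `I3 = (I2 - I1')/(2i)` and `I1`, `I2` solve the
forced natural-mode equation with right-hand sides `f` and `f'`. All
function algebra is done exactly on exponential polynomials
(`actifil.exppoly`): the resonant particular parts are `xi e^{k xi}/(4k^3)`
terms, the conjugate-mode parts `f*/(4 Sp^4 i)`, and the homogeneous
coefficients come from 4x4 boundary solves (growing modes anchored at
`xi = 1` for conditioning). The code asserts that every non-natural mode of
`I3` cancels (relative residual below 1e-7) and that `I3` is proportional
to the opposite-parity pair function before extracting the coupling
coefficients — a transcription error anywhere upstream fails loudly here.
The orientation of `I3` (the sign that decides which eigenvector is `g+`
and which its reflection) is pinned by requiring the analytic speeds to
agree with the kernel route and the time-average oracle; eigenvalue values
are insensitive to it.

The resulting real 4x4 eigenproblem couples the symmetric-mode
coefficients `(Af, Cf)` only to the antisymmetric ones `(Bf, Df)`, so the
implementation solves the 2x2 block product for `lambda^2` using the
stable trace/determinant formulas (`det(Bs Ba) = det Bs det Ba`). This
preserves the exact +-pair structure and keeps `lambda+` accurate over the
whole range. The subdominant `lambda-` is limited by cancellation in the
assembly to an absolute floor of about 1e-8: below roughly `Sp = 0.6` it
falls under that floor and is clamped to its (possibly zero) measured
value rather than failing — it only ever enters speeds as a multiplier, so
the clamp cannot corrupt a speed. The numeric eigendecomposition resolves
`lambda-` at those sperm numbers if needed. Eigenfunctions are normalized
to unit mean square with `int_0^1/2 g+ > 0` (making the symmetric double
`gs = g+(s) + g+(1-s)` positive, as the swimmer constructions assume).

## Optimizers

Piecewise-constant optima solve implicit equations in the cumulative
integrals of `gs` and `ga` (computed exactly from the exponential-
polynomial antiderivatives) by bisection on (0.5, 1) to 1e-9; the ratio
`ga/gs` decreases strictly across the bracket, so the sign change is
guaranteed and reported if absent. In the +1/-1 family the implicit
equation uses `int f gs` and `int f ga` with `f = +-1`, i.e. both
denominator integrals are against `gs`. First-order optimality of any
piecewise profile can be audited with `variational_check`, which evaluates
the sign conditions on an interior midpoint grid (the ratio `ga/gs` is
0/0 at the clamped ends).

Actuator placement exploits the variational structure: same-sign actuators
pack at the minimum spacing, positives left of negatives, leaving two
group-centre coordinates per sign split. The search enumerates splits with
at least half the actuators positive (a debug-free override via `split`
pins the count), grids the centres at 1e-3, and refines locally by
decade-shrinking grids to 1e-5 — deterministic, no random restarts, ties
toward smaller coordinates. Speeds come from the exact four-mode formula;
speed factors always divide by `lambda+` at the same sperm number. The L1
budget of the dominant eigenfunction is integrated by Simpson's rule on
20001 points (the integrand's kinks at the zeros of `g+` are the accuracy
limit; well below 1e-4 here).

## Synthetic profiles

`fixture_profiles` generates the study profiles: constant, sinusoids,
piecewise-constant (with exact segment bookkeeping), actuator lists, and
seeded smooth random profiles (Fourier series to 4 harmonics, coefficients
uniform in [-1, 1], default seed 20240256). Random profiles exercise the
bilinear identities and cross-route equivalences; they emulate smooth
distributed forcing, not measured flagellar moment distributions, so
passing tests certify the solver and kernel algebra — not any particular
biological forcing model. Real spermatozoa also swim at finite amplitude,
with a head, and often in three dimensions; none of that is captured at
this linear order.

## Known limitations

- Amplitudes are asymptotically small; finite-amplitude corrections are
  outside scope (classical experience suggests usable accuracy up to
  order-one forcing, but the package makes no such claim).
- `Sp` is certified in (0, 30]; `lambda-` degrades below `Sp ~ 0.6` as
  described above.
- Multi-frequency forcing is handled only by the linearity note: temporal
  modes decouple and dimensional speeds add; no combined solver is
  provided.
- The discrete-actuator search is deterministic and local after the coarse
  grid; for this problem (two coordinates, smooth objective) it recovers
  the global optimum, but pathological kernels with many ridges would need
  a denser coarse grid.
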