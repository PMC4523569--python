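# Methods

## Model

The package treats the radial Sturm–Liouville problem on the shell
`R <= r <= gamma R` (`gamma >= 1`) with Neumann (reflecting) boundary
conditions at both surfaces, in two geometries:

* **annulus** (2D): `Delta_r = d_rr + r^-1 d_r`, centrifugal term `nu^2/r^2`,
  weight `r`;
* **spherical shell** (3D): `Delta_r = d_rr + 2 r^-1 d_r`, term
  `nu(nu+1)/r^2`, weight `r^2`.

Eigenfunctions are the cross combinations
`Phi = Y'_nu(lam) J_nu(lam rho) - J'_nu(lam) Y_nu(lam rho)` (and the j, y
analogue), `rho = r/R`, which satisfy the inner Neumann condition by
construction; the outer condition quantizes `lam` as a zero of the derivative
cross product `f_nu` / `g_nu`.  Abel's identity for the Wronskian fixes the
inner boundary values `Phi(R) = 2/(pi lam)` and `psi(R) = 1/lam^2`, which in
turn give closed forms for the outer boundary value, the normalization
constant, and all Lommel integrals in terms of the single derivative ratio
`J'_nu(lam)/J'_nu(gamma lam)`.

The diffusion application expands the reflected-Brownian transition density
in this eigenbasis and projects the dipolar resonance-frequency shape
(`cos(2 phi)/rho^2` in 2D, `(3 cos^2 theta - 1)/rho^3` in 3D) onto it.  Only
the angular order nu = 2 survives the projection, so the frequency
autocorrelation is a single mode sum
`K(t) = domega^2 sum_n F_n^2 exp(-lambda_{n,2}^2 D t/R^2)`.

All computations are done in the nondimensional coordinate rho and
nondimensional time `tau = D t / R^2`; R and D re-enter only at I/O.

## Eigenvalue location

Standard root searches on `f_nu` can miss or double-count zeros and fail
outright for complex order.  The package therefore seeds from the original
operator: the radial Laplacian is discretized on `p` uniform nodes as a
tridiagonal matrix built from half-index radii, with a factor-2 closure in
the first and last rows that encodes the Neumann condition and makes every
row sum vanish exactly (the constant mode is annihilated in exact
arithmetic).  The eigenvalues of `[c_nu diag(1/r_j^2) - L]` approximate
`lam^2/R^2` to O(h^2).

* **Real order.** The nonsymmetric tridiagonal matrix is similarity-
  transformed with weights `sqrt(r_j)` (boundary rows `sqrt(r_j/2)`) to a
  symmetric tridiagonal and solved with LAPACK's banded bisection solver for
  the k smallest eigenvalues.  The grid is auto-scaled so that
  `lam_max * h < 0.1` (at least 2000 points), keeping the discretization
  error well below half the asymptotic root spacing `pi/(gamma-1)` even for
  hundreds of modes.
* **Complex order.** The complex-shifted matrix is solved densely
  (`p <= 2000`; 500–800 points suffice for seeding) and eigenvalues are
  ordered lexicographically by (Re, Im).  This ordering is a repository
  convention; no canonical enumeration of genuinely complex zeros exists.

Every seed is then polished on the analytic cross product: a sign-preserving
bracket plus Brent iteration for real order (root-jumping is impossible), a
plain secant iteration in the complex plane otherwise, with a root-collapse
guard rejecting a polished value that moved more than half the local spacing.
Convergence is judged against the local oscillation amplitude of the
objective, not an absolute threshold, because the cross product's scale
varies over many orders of magnitude with nu and lam.  The spherical cross
product behaves like `lam^-3` near zero, so polishing there operates on
`lam^3 g_nu(lam)`, which is scale-free and has the same positive-axis zeros.

The constant Neumann mode (`lam = 0`, present exactly when the centrifugal
coefficient vanishes) is excluded from the numbered modes and reported in the
table metadata; `n = 1` labels the smallest positive zero, the "exceptional
zero" that tends to `nu` (2D) or `sqrt(nu(nu+1))` (3D) as `gamma -> 1` —
note this differs from the classical handbook labeling, which starts the
count at the first non-exceptional zero.  A McMahon spacing check flags holes
in the real sequence; duplicate polished roots raise an error.

## Bessel and Lommel evaluation

Real orders use scipy's double-precision routines (complex arguments
included); complex orders fall back to mpmath at 30 significant digits.
Derivatives always come from the symmetric recurrences
`J' = (J_{nu-1} - J_{nu+1})/2` and
`j'_nu = (nu j_{nu-1} - (nu+1) j_{nu+1})/(2 nu + 1)` — never finite
differences — so the Wronskian identities hold to machine precision.

At a cross-product zero the J'-ratio and Y'-ratio coincide, but for
`nu >> lam` the zero can sit exponentially close to a zero of one of the two
outer derivatives; the ratio is therefore computed from whichever pair has
the larger denominator.  Without this choice the normalization constants of
high-angular-order modes overflow and the propagator series degrades
catastrophically.

Lommel functions `S_{kappa,nu}` (even in nu) are evaluated by route:

1. registered polynomial closed forms — `S_{1,2m} = z O_{2m}(z)` (Neumann
   polynomials, generated from Watson's explicit sum), `S_{0,2m+1}`,
   `S_{-1,2m} = S_{2m}(z)/(4m)` (Schlafli), and the general odd
   `kappa + nu = 2p+1` Gegenbauer form;
2. the 1F2 series `s_{kappa,nu}` plus the Gamma-weighted J,Y complement,
   truncated at relative term size 1e-16 (≤ 500 terms); `|z| > 40` raises a
   range warning since no asymptotic continuation is implemented;
3. when the complement hits a Gamma pole, kappa is shifted upward by 2 (at
   most 3 times) and the three-term recurrence is unwound.

Derivatives `S'` come from the index-lowering recurrences (either one
suffices together with S itself; both are tried because one lowered pair may
be exceptional).  Pairs with `nu - kappa` an odd positive integer whose shift
chain crosses `(kappa+1)^2 = nu^2` — the `S_{-1,0}` family, whose integrals
involve Si/Ci — have no finite route here and raise a pole error naming the
pair.  Closed forms on that manifold (e.g. `S_{1,2}`) are validated against
the defining inhomogeneous Bessel equation instead of the series.

For complex (kappa, nu) only the series route is exposed; the branch
conventions of the closed forms are not established for complex indices.

## Normalization, Lommel integrals, orthogonality

Closed forms are those of the boundary-term expressions specialized to
Neumann values; each is cross-checked against adaptive quadrature
(`epsabs 1e-12`, `epsrel 1e-10`) — the oracle deliberately out-precises the
1e-7/1e-8 claims being tested.  The verification grid spans both geometries,
orders {0, 1, 2, 3.5}, ratios {2, 5, 8} and the first three modes; for the
spherical Lommel integral the moment alpha is chosen per order (1, 0, -1, -1
respectively) so the half-integer Lommel pair has a finite route.  The Gram
matrix uses the bilinear (non-conjugated) product, which is the pairing under
which the complex-order eigenfunctions are orthogonal.

## Dipole expansion and sum rules

`F_n^2` is computed from the derivative-ratio form and cross-validated
against the algebraically equivalent cleared form (2D) or trigonometric form
(3D) to 1e-10 per mode.  (The derivative-ratio form carries the
`1/lambda^2` prefactor required by dimensional consistency of the two
forms.)  Four closed-form sum rules (three in 3D) certify truncations.
Direct partial sums converge like `n^-3` or faster except the
`lambda^2`-weighted rule, whose terms fall off only as `n^-2`: asymptotically
`F_n^2 lambda_n^4` approaches two interleaved constants (the zeros alternate
between the two branches of the large-argument Bessel phase), so the dropped
tail is completed by fitting `a + b/lam + c/lam^2` per parity of n over the
last 160 computed modes and summing the fit over McMahon-extended zeros
(2e6 terms plus an analytic remainder).  With 400 modes all rules then agree
with their closed forms to better than 1e-9.

## Propagator

The transition density sums angular orders with `(2 - delta_{nu 0}) cos(nu
dphi)` factors (2D) or `(2 nu + 1) P_nu(cos Omega)/(4 pi)` Legendre factors
(3D, scipy's `eval_legendre`; integer physical orders only), truncating each
radial series when the damping factor `exp(-lam^2 tau)` falls below 1e-12 and
warning when the cutoff modes are not yet damped (short times need more
modes).  A vectorized grid evaluator computes the density on an (r, angle)
tensor grid with each radial eigenfunction evaluated once per mode;
normalization constants are cached.  Probability conservation on the shell
holds to 1e-10 with 40 angular orders at `tau = 0.2`.

## Monte Carlo validation oracle

An independent reflected-Brownian simulation (no eigenfunctions anywhere)
validates K(t): Gaussian steps of standard deviation `sigma = 0.01 (gamma-1)`
per coordinate (time increment `sigma^2/2`), specular radial reflection at
both shells, uniform volume-weighted initial positions, and accumulation of
`f(x_0) f(x_t)`.  With 1e5 walkers the mode-sum K agrees within one standard
error at `tau` in {0.05, 0.2, 1} in both geometries; the test tolerance is
three standard errors.  The walk emulates ideal reflected Brownian motion
only — no permeable walls, surface relaxation, susceptibility-gradient
feedback on trajectories, or finite-pulse effects — so agreement validates
the propagator mathematics, not the fidelity of the dipole model to any
particular tissue.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `gamma` | — | outer/inner radius ratio; reference cases use 5 (generic), 8 (capillary figure), `eta^(-1/3)` (volume fraction) |
| `p` | 2000 (auto-scaled up) | grid points for matrix seeding |
| polish tolerance | 1e-12 (relative to local amplitude) | cross-product residual at a polished zero |
| `n_max` | 200–400 | dipole-expansion depth; 200 suffices for the quartic sum rule at 1e-6, 400 for all rules with tail completion |
| `D` | 1 length²/time | diffusion coefficient; only `D t / R^2` matters |
| `delta_omega` | 1 rad/time | dipole field strength; K scales as its square |
| MC step `sigma` | `0.01 (gamma-1)` | random-walk step; bias is O(sigma) at the walls, well below 3 SE at 1e5 walkers |

## Known limitations

* Complex-order seeding uses a dense eigensolver, practical to `p ~ 1000`;
  extremely large complex `|nu|` is untested.
* No uniform asymptotic expansions: Lommel series is limited to moderate
  `|z|`; very high orders at small arguments rely on mpmath only for complex
  nu, while real-order scipy calls can underflow for `nu >> 100`.
* The exceptional Lommel pairs (Si/Ci family) are not implemented; the
  corresponding integrals raise a documented error.
* Dirichlet and Robin boundary conditions, and non-dipole shape functions,
  are out of scope.
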