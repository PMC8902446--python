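# Methods

## Model

The object of study is the partitioned linear Langevin system

    dz/dt = J (z − ρ) + ω_t,          Cov(ω_t) = 2Γ  (diagonal),

with state order fixed as z = (y, s, a, x): external, sensory, active and
internal blocks; the blanket is b = (s, a), contiguous in this ordering.
The drift is written J = −I + C so that C collects the couplings; the
homogeneous-noise case Γ = ς²I is the default study condition and the only
mode the weak-coupling series support. J must be Hurwitz (all eigenvalues
with negative real part), otherwise no stationary density exists and the
constructors refuse the system.

The stationary density is Gaussian N(ρ, Σ*) with Σ* solving the continuous
Lyapunov equation JΣ* + Σ*Jᵀ + 2Γ = 0. We define the solenoidal matrix as

    Q := JΣ* + Γ.

This convention is chosen deliberately: it is antisymmetric as an immediate
consequence of the Lyapunov equation, it reproduces the standard
weak-coupling series Q = ½(CΓ − ΓCᵀ) + ¼(C²Γ − Γ(C²)ᵀ) + O(C³) term by
term, and it makes the drift-reconstruction identity (Q − Γ)H = J exact,
which in turn gives the gradient-flow rate factor −(Q_yy − Γ_yy) the right
sign. The opposite sign convention (the solution of JQ + QJᵀ = JΓ − ΓJᵀ)
is exposed through a `q_sign` switch for comparison; the Lyapunov form our
Q satisfies is JQ + QJᵀ = ΓJᵀ − JΓ.

## Structures and the synthetic generator

Three sensorimotor structures are expressed as masks on C:

* **canonical** — the perception–action interface: f_y, f_s depend only on
  (y, s, a) and f_a, f_x only on (s, a, x); zero blocks C_yx, C_sx, C_ay,
  C_xy.
* **circular** — a unidirectional loop y→s→x→a→y; only C_sy, C_xs, C_ax,
  C_ya may be nonzero between blocks, within-block entries free. The
  orientation is a package choice (the mirror orientation y→a→x→s→y is
  available via `circular_direction="yaxs"`); nothing downstream depends on
  which one is used, because the scaling laws are orientation-symmetric.
* **symmetric_chain** — canonical zeros plus C_ya = C_xs = 0 and symmetric
  between-block couplings C_ys = C_syᵀ, C_sa = C_asᵀ, C_ax = C_xaᵀ;
  asymmetry survives only inside blocks. This is the structure for which
  the first-order solenoidal couplings between blocks vanish.

The generator draws every mask-allowed entry of C (including within-block
diagonals) as ε times an independent Rademacher sign, mirrors the symmetric
pairs from a single draw, sets J = −I + C, Γ = ς²I and ρ = 0. Defaults
ε = 0.1, ς = 0.1 and the partition n_y = n_x = 2, n_s = n_a = 1 are the
reference study conditions. The full n×n sign pattern is drawn before
masking, so a fixed seed yields the *same* pattern at every ε — ε-sweeps
then isolate pure ε-scaling from sign-pattern noise, which is what makes
the fitted log-log exponents clean with ~20 seeds. At these couplings the
drift is diagonally dominant and the Hurwitz check never needs a resample
(verified over 10³ seeds); the retry loop exists for deliberately strong
couplings.

What the generator does **not** emulate: state-dependent noise,
correlated (non-diagonal) Γ, nonlinear drifts, and coupling magnitudes
beyond the weak regime. Passing tests therefore certify the linear
weak-coupling theory, not any claim about strongly coupled or nonlinear
systems.

## Exact solvers

Σ* comes from SciPy's Bartels–Stewart Lyapunov solver, is symmetrized, and
its positive-definiteness is checked via the smallest eigenvalue exceeding
1e-12 times the largest; failures (e.g. ς = 0) raise a degenerate-density
error rather than silently pseudo-inverting. H is obtained from a Cholesky
solve, never an explicit inverse. An O(n⁶) Kronecker-vectorization solve of
the same equation is kept in the test suite as an independent oracle
(n ≤ 6), as is the independent Lyapunov equation for Q.

## Weak-coupling series

All series are built by exact order-tracked recursions, never by
numerically subtracting exact solutions:

* Σ*: S₀ = Γ, S_k = ½(C S_{k−1} + S_{k−1} Cᵀ) — the unique fixed-point
  decomposition of the Lyapunov equation at J = −I + C;
* Q: Q_k = C S_{k−1} − S_k, which is antisymmetric *exactly* at every
  order (the recursion gives Q_k + Q_kᵀ = 0 identically);
* H and (Σ*_bb)⁻¹: Neumann inversion of the (restricted) Σ series,
  requiring Γ = ς²I so the order-0 term is a multiple of the identity.

Truncation at order k leaves an O(ε^{k+1}) remainder; the tests verify the
ratio error(ε)/error(ε/2) ≈ 2^{k+1} over seeds.

## Audit definitions

"Markov blanket holds" is operationalized as ‖H_yx‖_F ≤ tol·‖H‖_F with
default tol = 1e-8 — an *exact-claim* tolerance, since no finite threshold
is canonical; approximate claims are reported as raw residuals and scaling
exponents instead. Solenoidal decoupling is audited in two modes, both
first-class: the full block-diagonal requirement (blocks ys, ya, yx, sa,
sx, ax must vanish) and the weaker autonomous/non-autonomous split (only
ya, yx, sa, sx), which tolerates Q_ys and Q_ax. Verdict scales use
max(‖Q‖, ‖Γ‖) so equilibrium systems (Q ≈ 0) are not judged against a
vanishing reference.

Measured scaling laws (log-log slope of the median residual over matched
seeds): the canonical blanket violation is second order (slope 2); the
circular loop pushes it to third order (slope 3) because the shortest
conditional path between y and x is the 3-step cycle; the symmetric chain
pushes it to *fourth* order — a fully symmetric C gives H ∝ −J exactly, so
any violation needs at least one asymmetric within-block factor on top of
the 3-step chain. Solenoidal off-blocks: first order for generic canonical
systems (Q_ya ≈ ς²/2 C_ya), second order under the symmetric chain.

## Inference geometry

Conditional moments use the Schur complement Σ_{y|b} = Σ_yy − Σ_yb Σ_bb⁻¹
Σ_by, which is correct with or without a Markov blanket; the
precision-route alternative (H_yy)⁻¹ coincides with it only when H_yx = 0,
so their gap is reported as an extra blanket diagnostic. The blanket block
is pseudo-inverted (and flagged) when its condition number exceeds 1e12.

Surprise, KL and free energy are closed-form Gaussian expressions; for
linear systems the quadratic ("Laplace") form of the surprise is exact, so
no approximation is involved and the gradient ∇_θF = Σ_{y|b}⁻¹(θ − m_y(b))
is the exact gradient, not a second-order expansion.

The gradient-flow identity residual probes
f_y(θ, b) = (Q_yy − Γ_yy)∇_θF at 16 deterministic Halton points within ±3
standard deviations (blanket-marginal for b, conditional for θ), reporting
the worst-case relative gap. It is exactly zero whenever H_yx = 0 and the
Q blocks coupling y to (b, x) vanish — then J_yy = (Q_yy − Γ_yy)H_yy and
J_yb = (Q_yy − Γ_yy)H_yb follow from (Q − Γ)H = J — and grows linearly in
ε for generic canonical systems. In that identity regime the adjustment
rate of Eq.-of-motion form dθ/dt = −γ∇F is γ = Γ_yy − Q_yy.

The flow map φ with ⟨f_y⟩_b = φ(⟨f_x⟩_b) is built from the exact flow
coefficients: ⟨f_y⟩_b = (J_yy G_y + J_yb)(b − ρ_b) with gain G_y =
Σ_yb Σ_bb⁻¹, and likewise for x, giving φ = (J_yyΣ_yb + J_ybΣ_bb)
(J_xxΣ_xb + J_xbΣ_bb)⁻¹. This is the algebraically consistent composition;
a form that omits the J_yb/J_xb factors transports flows correctly only
when those blocks equal the identity. φ is restricted to square invertible
blocks (n_y = n_b = n_x); non-square or rank-deficient configurations
raise a mapping-undefined error rather than guessing a pseudo-inverse
generalization. Note that a Rademacher draw occasionally produces an
*exactly* rank-deficient Σ*_xb (sign patterns can align); such systems are
excluded from mismatch statistics since φ does not exist there. For the
symmetric chain both flow coefficients are themselves O(ε²), so φ is
ill-conditioned; the φ-vs-∇σ mismatch is therefore quoted for canonical
systems.

## Trajectories and the surrogate comparison

Euler–Maruyama with per-step noise covariance 2Γ·dt; defaults dt = 1e-2,
T = 100, 32 ensemble members — enough to resolve the divergence
phenomenology in seconds. A step with dt·max|eig(J)| ≥ 0.1 warns and is
flagged. The deterministic limit is validated against the e^{Jt} closed
form (O(dt) convergence) and the ensemble covariance against Σ*.

The comparison never finite-differences noisy paths: m_y(b_t) is evaluated
pointwise as a fixed linear image of the blanket path, and the surrogate
m̃_y integrates its ODE driven by the *realized* blanket path from the
shared initial condition m̃_y(0) = m_y(b_0). Ensemble variance is averaged
over coordinates; the growth slope is fitted on the second half of the run
and the diffusive signature is the ratio Var(T)/Var(T/4) ≈ 4. In the
validity-boundary case ς = 0 ∧ C_yb = 0 the trajectory is a deterministic
decay to ρ, so the gap accumulates only over the O(1) transient; the
meaningful statement, which the tests assert, is that this residual gap is
O(ε²) (conditional gains for that comparison are taken from the same
couplings at a reference ς > 0, legitimate because gains are invariant
under scaling Γ).

The bivariate spiral demonstration uses J = [[−1, c], [−c, −1]] over two
variables (y, b) — a concrete choice made here; its C is antisymmetric, so
Σ* = ς²I exactly, Q = ς²c[[0,1],[−1,0]], and the eigenvalues −1 ± ci give
a globally attracting spiral. Because Σ_yb = 0, the conditional mode is
m_y(b) = 0 and the conditional average flow of y given b is c·b: a field
that reads as monotone growth in |y| away from b = 0 even though every
trajectory decays to the origin in expectation. The demo reports field
sign structure, not magnitudes.

## Numerical choices and limitations

* Tolerances: Lyapunov/antisymmetry residuals 1e-10 (relative to noise
  scale), drift reconstruction 1e-8, positive-definiteness cutoff 1e-12
  relative; these are solver-precision margins, not physical thresholds.
* Exponent fits use medians over matched seeds on a 3-point ε grid
  {0.025, 0.05, 0.1}; slopes are insensitive to the grid because the sign
  patterns are matched.
* ρ = 0 is the default everywhere (mean-zero study conditions); nonzero ρ
  is carried through all conditional/flow formulas and covered by tests.
* Heterogeneous diagonal Γ is accepted by the exact solvers but not by the
  series (which need Γ ∝ I); non-diagonal Γ and nonlinear drifts are out
  of scope.
* The package audits given partitions only; it does not search for
  blankets.
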