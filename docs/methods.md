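# Methods

## Model and assumptions

The tumor is modeled as two logistic compartments with a joint carrying
capacity scaled to 1: sensitive cells `x1` and fully resistant cells
`x2`, with controlled dynamics `dx/dt = f(x) + u(t) g(x)`,

    f(x) = ((1 − x1 − x2) x1 − ε x1,  p_r (1 − x1 − x2) x2 + ε x1)
    g(x) = (−(α + d) x1,  α x1).

Assumptions baked into the implementation:

- complete resistance (`x2` is unaffected by the drug) and the log-kill
  hypothesis (kill rate `d·u·x1`);
- induced transitions proportional to dose (`α·u·x1`) on top of the
  spontaneous rate `ε·x1`;
- `0 ≤ p_r < 1` (resistant cells divide no faster than sensitive ones),
  `d > 0` (several formulas divide by the cytotoxicity, so a drug with
  no kill effect is rejected at construction), `0 < V_c < 1 − ε`;
- no pharmacokinetics: the dose `u(t) ∈ [0, M]` acts instantaneously.

The simplex `Ω = {x ≥ 0, x1 + x2 ≤ 1}` is forward invariant and, for
`ε > 0`, every trajectory converges to the fully resistant state (0, 1)
regardless of dosing; the convergence timescale of the *untreated*
system is `~1/ε`, which matters when choosing test horizons (see
below).  Therapy is scored by the failure time `t_c`, the last time the
volume `V = x1 + x2` has remained below the critical volume `V_c`.

## Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| `pr`    | relative resistant growth rate | 0.2 | — |
| `eps`   | spontaneous transition rate | 1e-6 | 1/time |
| `alpha` | drug-induced transition rate | 1e-2 | 1/(dose·time) |
| `d`     | log-kill cytotoxicity | 1.0 | 1/(dose·time) |
| `M`     | maximum dose | 5.0 | dose |
| `Vc`    | critical volume | 0.9 | fraction of capacity |
| `x10`, `x20` | initial fractions | 1e-2, 0 | fraction |

The defaults are the baseline conditions of the numerical experiments
the package reproduces; `d` and `alpha` are the axes most experiments
vary.  Time is in units of the sensitive growth rate (the system is
non-dimensionalized), so reported `t_c` values are dimensionless.

## Geometry of the synthesis

Wherever `x1 > 0` the frame `(f, g)` is invertible and the Lie bracket
decomposes as `[f, g] = γ f + β g`.  The zero set of `γ` is the line
`a x1 + b x2 = c` with

    a = α((1 − p_r) + d/(α + d)),  b = α(1 − p_r) + d p_r,
    c = α(1 − p_r) + ε d,

the only place singular arcs can live.  The admissible singular segment
is the portion where the max-dose field has `L_Y γ > 0`; its lower
endpoint `s̄` (where `L_Y γ = 0` and the singular dose saturates at `M`)
has no closed form and is found by bracketed root-finding (Brent) to
`1e-10` in `x1`.  Gradients of `γ` are obtained by symbolic
differentiation of the closed form (sympy), lowered once to a cached
numpy function; a central finite-difference cross-check (step `1e-6`)
runs in the tests only.  The Legendre–Clebsch quantity
`(L_Y γ − L_X γ)/M` is positive along the segment, certifying that
singular dwell is sub-optimal; the clock form
`ω = (g2 dx1 − g1 dx2)/det(f, g)` converts that statement into explicit
time comparisons (a singular dwell is strictly faster than the matched
bang-bang excursion, hence loses objective time).

Two printed formulas in the source material are typographically
ambiguous and were re-derived rather than transcribed: the singular
feedback (derived from tangency `a ẋ1 + b ẋ2 = 0`, giving denominator
`2 α d (1 − p_r) x1`, and cross-validated against the equivalent
Lie-derivative form `M L_X γ/(L_X γ − L_Y γ)`), and the admissibility
threshold for the singular segment (implemented operationally as
`L_Y γ > 0` at the line's `x2 = 0` endpoint).  Likewise the recovery of
`p_r` in the identifiability layer uses the re-derived closed form of
`L_g L_f h`, validated by the round-trip property and by machine
symbolic differentiation.

## Simulation

Piecewise controls are integrated arc by arc with `scipy`'s LSODA and
event root-finding:

- **Bang/constant arcs** terminate early at an upward crossing of
  `ψ = V − V_c`.  If a sliding arc is queued and the boundary feedback
  `u_p` is admissible at the contact point (equivalently `x1 ≥ x1*`,
  the tangency abscissa), the trajectory switches to sliding; otherwise
  the crossing is the failure time.  An arc that *starts* on the
  boundary with non-decreasing volume fails immediately (this covers
  the post-sliding terminal arc, which departs from the tangency point
  where `dV/dt = 0` and `V` immediately rises — the extra sliding time
  lost by recording `t_c` at saturation is measure zero).
- **Sliding arcs** apply the feedback `u_p` exactly (not by
  projection), so `dV/dt = 0` analytically and numerical drift off
  `V = V_c` stays below `1e-7`.  The arc ends at the root of
  `u_p = M`.  If activated away from the boundary the arc first drifts
  with `u = 0` to the boundary ("boundary-seeking"): in the optimal
  word the arc preceding the slide is a no-dose arc whose end is the
  event-determined boundary contact, not a free switch time.
- Default tolerances `rtol = atol = 1e-10`, step cap 10 time units
  (events must not be skipped over long arcs); halving tolerances moves
  `t_c` by less than `1e-4` relative on the baseline preset.  The
  vector field is evaluated on the non-negative part of the state so
  that integrator underflow below zero cannot re-enter as spurious
  exponential growth.
- Clock-form time integrals use a midpoint rule on stored polylines
  with at least 2000 points per arc, which keeps the elapsed-time
  identity within 0.5%.

## Optimizer

`optimize` maximizes `t_c` over the structured words: the sliding
family with `n = 0, 1, 2` leading bang pairs (free parameters: the
bang arc durations, 0/1/3 of them — the approach arc is
event-determined) plus the pure bang words `Y`, `X`, `YX`, `XY` and
`YXY` (the last covers the open question of a bang-bang junction
without sliding).  Search is a deterministic coarse grid (24 points for
1-D, 16 per dimension for 2-D, 8 per dimension for 3-D) followed by
two sweeps of coordinate-wise bounded scalar refinement (`xatol =
1e-4`) on a window of one grid spacing around the incumbent; the
winner is re-simulated at the default tolerances, and the reported
`t_c` always re-validates through `time_to_failure` to `1e-6`.  These
problem sizes were chosen so a full 15-cell parameter grid runs in a
few minutes on one core while reproducing the published optima to well
within 2%; the landscape is smooth near optima but can be cliff-like
where deep max-dose arcs crush `x1` to below `1e-12` (hence the tight
search `atol = 1e-13` and the localized refinement windows).  Durations
are bounded by 1.5x the constant-dose failure times.  There is no
randomness anywhere: repeated runs are byte-identical.

The regularized objective `J_η = −∫ [1 − (1 − η)² u²] dt` is provided
for evaluation only (it reduces to `−t_c` at `η = 1`); solving the
regularized problem is an external-solver accuracy probe, not part of
the synthesis.

## Maximum-Principle diagnostics

The adjoint lift is a *verifier*, not a solver: for a bang control the
initial covector is parametrized by the initial switching value `φ0`
under the normalization `H = 0`, `λ0 = 1` (unique since `f, g` are
independent for `x1 > 0`).  Because the adjoint flow is linear, the
switching value at a prescribed junction is affine in `φ0`, so the lift
with a genuine junction is found from two evaluations.  Checks: `H ≡ 0`
to `1e-6` along arcs, the switching ODE `Φ' = γ + (β − uγ)Φ` to `1e-6`
(left side computed independently via `⟨λ, [f, g]⟩`), sign consistency
of `Φ` with the applied bang values, and `Φ'(τ) = γ(x(τ))` at
junctions.  Verification is restricted to interior (pre-boundary)
sub-arcs, where the unconstrained Maximum Principle applies; no
terminal transversality data is available for constrained arcs.

## Identifiability

With volume as the only output and an entirely sensitive start
`(x10, 0)`, five iterated Lie derivatives of `h = x1 + x2` at `t = 0`
determine all parameters in closed form; `recover` inverts them
exactly.  The recovery of `α` is a difference `(α + d) − d`, so its
one-ulp float64 error is amplified by `1/(α(1 − x10))` in `p_r` and by
`1/(d·x10)` in `ε`; round-trip tests therefore carry an absolute floor
of `1e-10` on top of `1e-9` relative — conditioning of the map, not
method error.  Estimating the Lie derivatives from noisy measured
volume curves (practical identifiability) is out of scope: the claim
implemented is structural.

## What the tests do and do not show

All inputs are the model's own parameter sets — there is no external
data — so the tests demonstrate internal correctness (closed forms
against symbolic and finite-difference oracles, event handling against
closed-form logistic times, optimizer output against an independently
published grid of optima computed with a general-purpose collocation
solver) under the stated modeling assumptions.  They do not validate
the biology: complete resistance, dose-proportional induction and the
absence of pharmacokinetics are idealizations, and `t_c` values are in
non-dimensional time.

Numerical edge cases handled deliberately: `α = 0` (no induction — the
singular line degenerates and the synthesis is purely bang-bang plus
sliding), `p_r = 0` (the tangency point collapses to `x1* = 0` and
sliding never saturates), states with `x1 = 0` (the frame degenerates;
geometry functions raise rather than extrapolate), and boundary starts
(immediate failure when the volume cannot decrease).  The
asymptotic-resistance property is tested at `ε = 1e-3` because at the
baseline `ε = 1e-6` the untreated system needs `t ~ 1/ε = 1e6` to
equilibrate, far beyond any therapy horizon of interest.

## Known limitations

- The optimizer searches the proven structural family (plus bang-bang
  words); it is not a general direct-collocation solver and will not
  discover structures outside that family.
- Whether a true `YXY` junction below the singular line is ever
  optimal remains open; the family admits it but no tested parameter
  set selects it.
- Controls are piecewise arcs (bang, constant, boundary feedback,
  singular feedback); arbitrary functional controls are out of scope.
- One drug, two phenotypes, no reverse (resistant→sensitive)
  transitions.
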