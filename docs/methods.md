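# Methods

## 1. Model

Eleven compartments: susceptible S, protected P, smoking classes
(exposed ES, addicted IS, permanently addicted PS), alcohol classes
(EA, IA, PA), dual-addiction classes (addicted CSA, permanently addicted
PSA), and rehabilitated T. Total population N is the sum of all eleven.

Forces of addiction use standard (frequency-dependent) incidence:

```
λA = β1 (IA + PA + θ1 (CSA + PSA)) / N        (alcohol)
λS = β2 (IS + PS + θ2 (CSA + PSA)) / N        (smoking)
```

Susceptibles are recruited at rate (1−π)K, protected at πK; protection is
acquired at rate δ and modified susceptibility of the protected class is
ρ1 (alcohol) and δ1 (smoking). Addicted singles can progress to dual
addiction through cross-exposure with modification factors ρ2, ρ3 (alcohol
force acting on smoking classes) and δ2, δ3 (smoking force on alcohol
classes). Improvement (rehabilitation) rates are ε1 (IA), ε2 (IS), ε3
(CSA); addiction-induced death rates are dS, dPS, dA, dPA, dC, dSA; μ is
natural death. Two six-compartment sub-models (S, P, E, I, P-addicted, T)
restrict to a single addiction by dropping the dual terms from the force.

The baseline calibration (defaults of `ModelParameters`) is
μ=0.0135, K=20, π=0.5, δ=0.21, δ1=δ2=δ3=1.1, ρ1=ρ2=ρ3=1.2, ε1=0.223,
ε2=0.01, ε3=0.313, β1=0.75, β2=0.38, α1=0.0002, γ1=0.01, α2=0.56, γ2=0.321,
α=0.54, θ1=θ2=1.05, dA=0.075, dS=0.035, dPA=0.091, dPS=0.87, dC=0.11,
dSA=0.23. The source calibration lists two conflicting values for α1
(0.0002 and 0.0003); the default uses 0.0002 and the alternative is kept as
`model_core.ALT_ALPHA1`.

## 2. Addiction-free equilibrium and reproduction numbers

The addiction-free equilibrium (DFE) is

```
S0 = (1−π)K/(δ+μ),   P0 = K(δ+πμ)/(μ(δ+μ)),   S0 + P0 = K/μ.
```

Reproduction numbers come from the next-generation-matrix (NGM)
construction on the (E, I, P-addicted) block of each sub-model. The
certified closed form (re-derived from the NGM; it also follows from the
published factorisation) is

```
R0A = β1 α1 (α2+μ+dPA) [μ(1−π) + ρ1(δ+πμ)]
      ───────────────────────────────────────────────
      (μ+α1)(α2+ε1+μ+dA)(μ+dPA)(δ+μ)
```

and symmetrically for R0S with (β2, γ1, γ2, ε2, δ1, dS, dPS). The dual
model threshold is R0AS = max(R0A, R0S). The implementation certifies the
closed form against a numeric NGM (finite-difference F and V at the DFE,
spectral radius of F·V⁻¹) to 10⁻⁸ relative accuracy; at the baseline
calibration R0A ≈ 0.09538 and R0S ≈ 0.63724.

Known discrepancy: the source text states baseline reproduction numbers of
1.74 and 1.53; neither is reproducible from the listed calibration under
any printed closed form (nor under the NGM). The oracle-certified closed
form above is treated as authoritative.

## 3. Endemic equilibria and bifurcation analysis

At an endemic equilibrium of a sub-model the compartments solve a
triangular system given the equilibrium force λ, so the equilibrium
condition reduces to a scalar fixed point g(λ) = 0. Clearing denominators
turns g into a quadratic Q(λ) = c2 λ² + c1 λ + c0 with c2 > 0 and
sign(c0) = sign(1 − R0). The coefficients are recovered numerically by
fitting Q at three points (exact for a quadratic); roots are located
independently by a dense sign scan plus bisection, and the two methods are
cross-checked in the tests. Two positive roots with R0 < 1 certify a
backward bifurcation (coexistence of a stable DFE with a stable endemic
state below threshold).

The center-manifold (Castillo-Chavez–Song) coefficients a and b are
computed at the critical dissemination rate β* = β/R0 (R0 is linear in β):
right/left null vectors u, v of the full 11×11 DFE Jacobian (v·u = 1), then

```
a = v · D²h(x0)[u, u]     (directional second central difference)
b = v · ∂(Dh u)/∂β        (mixed four-point difference)
```

Sign convention: u is normalised so its dominant exposed component is
positive, which makes b > 0 an invariant and lets sign(a) classify the
bifurcation (a > 0 backward, a < 0 forward). Note a > 0 is a local
statement at R0 = 1: a backward regime whose saddle-node fold lies above
the sampled R0 can still show zero endemic roots there (the tests evaluate
the root count at R0 = 0.999 when comparing detectors).

The `backward-candidate` fixture regime (slow demography, strong
protection waning, fast progression: μ ∈ 10^[−2.5,−1], π ∈ [0, 0.5],
δ ∈ 10^[−1,0.7], ρ1 ∈ 10^[−1.5,0.5], α1 ∈ 10^[−1,0.7], α2 ∈ 10^[−2,0],
ε1 ∈ 10^[−3,−1], dA, dPA ∈ 10^[−1,0.7], β1 rescaled to R0A = 0.98, β2
rescaled to R0S = 0.49 so the alcohol pathway stays dominant) yields
backward regimes for roughly one draw in six; `find_backward_parameters`
searches until the two-root certificate holds.

## 4. Sensitivity

Elasticities (∂R0/∂p)(p/R0) are computed by symbolic differentiation of
the closed form (lambdified once per branch) and cross-checked by central
finite differences at relative step 10⁻⁶. The dissemination rate has
elasticity exactly 1 (linearity); the recruitment rate K cancels under
standard incidence and has elasticity exactly 0.

## 5. Optimal control

Six controls in [0, 1]: protection education against smoking (w1), alcohol
(w2) and dual addiction (w3, gating the S→P protection flow), and
treatment of smoking (w4), alcohol (w5) and dual (w6) addicted classes.
The controlled system is transcribed as published; two consequences are
kept deliberately:

- at w = 0 the protection flow δS and all improvement flows (ε terms)
  switch off, so the zero-control system equals the uncontrolled model
  with those flows removed (verified by test);
- the CSA inflow from IS/PS carries (1−w2) while the matching outflow from
  IS/PS carries (1−w4)/(1−w2) respectively — a mass-balance imbalance of
  the published controlled system, kept as printed.

The objective is J = ∫ (Σ Dᵢ·addictedᵢ + ½ Σ ψᵢ wᵢ²) dt with defaults
Dᵢ = 7, ψᵢ = 10 and free terminal state (zero transversality). The
Hamiltonian H = running cost + f·χ is the single source of truth:

- **Adjoint**: f′ = −∂H/∂x generated symbolically (sympy, CSE-lambdified),
  including the ∂λ/∂x standard-incidence corrections. A transcription of
  the published costate equations is kept as `adjoint_rhs_printed`; it
  drops those dN corrections and contains slips (a w5ε2 where the dynamics
  use w4ε2, an N in place of S in one bracket and vice versa, a stray
  β1α1 factor), so it is reconciled with the exact gradient only on the
  costates of S, P, ES, EA and T at addiction-free states.
- **Control update**: H is an exact quadratic ψᵢ/2·wᵢ² + Lᵢwᵢ + c in each
  control with no cross terms; Lᵢ is extracted from two Hamiltonian
  evaluations and the update is w* = clip(−Lᵢ/ψᵢ, 0, 1).
- **Sweep**: forward RK4 of the state (midpoint control interpolation),
  backward RK4 of the adjoint from f(T)=0, relaxed update
  w ← (1−c)w + c·w_new with c = 0.5, convergence when the largest control
  change is below 10⁻³, at most 100 iterations.

Strategies A–I combine the controls: A = protections {1,2,3},
B = treatments {4,5,6}, C/D/E = protections plus one treatment (4/5/6),
F/G/H = protections plus two treatments ({4,5}/{4,6}/{5,6}), I = all six.

## 6. Cost-effectiveness

For a strategy, total addictions averted = ∫(A_baseline − A_controlled) dt
with A = IS+PS+IA+PA+CSA+PSA and the baseline the same controlled system
at w ≡ 0; total cost = ∫ ½ Σ ψᵢwᵢ² dt. ICER tables rank strategies in
ascending averted order; the first row's ICER is cost/averted (against the
do-nothing sentinel) and later rows are Δcost/Δaverted against the
previous surviving row. Each elimination round removes the largest-ICER
(dominated) strategy until one survives.

Replaying the published outcome cells reproduces every
arithmetic-consistent printed ICER to four significant figures and every
narrated elimination: four-control case removes E then C (winner D),
five-control case removes G then H (winner F), and the cross-case
comparison of winners removes the all-controls strategy, then D, then F,
leaving the protection-only strategy A. Known discrepancies, documented
and excluded from targets: the three-control case's printed ratios are a
factor of ten high and its narrated winner (A) contradicts its own
elimination rule (recomputation removes A, leaving B); a handful of other
printed cells (four-control C and second-round D, five-control G,
cross-case all-controls row) are arithmetically inconsistent with their
own averted/cost entries, while the elimination decisions they support are
unaffected.

## 7. Numerics and reproducibility

- Fixed-step classical RK4 throughout (matching the published simulation
  approach); default horizon 5 time units with 1001 grid points. Tests use
  coarser grids (≈100–400 points) chosen for runtime; results quoted in
  the documentation use the defaults. Accuracy is certified against an
  adaptive high-tolerance integrator in the tests.
- Positivity and the population bound N ≤ max(N(0), K/μ) are enforced as
  test invariants, not clipped during integration.
- All stochastic fixtures derive from a single integer seed
  (`numpy.random.default_rng`, derived seeds kept below 2³¹); analyses
  themselves are deterministic.
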