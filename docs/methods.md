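# Methods

## Model

The package implements an asymmetric four-population evolutionary game of
service-quality regulation in "Internet + Community Elderly Care". Each
population is large, well mixed and boundedly rational; a state is the
vector of first-strategy shares s = (x, y, z, w) ∈ [0,1]⁴ for providers
(high quality), platforms (positive return visits), government (positive
regulation) and the elderly (online evaluation).

Stage payoffs are given by a 16-cell matrix built from the following
assumptions:

- Provider and platform split service revenue Rs with commission share α.
  High quality costs Csh, low quality Csl (Csh > Csl). Low quality triggers
  compensation Io to the elderly, a government fine Fs (when detected), and
  reputational loss Ds; high quality earns reputational gain Is.
- A visiting platform pays Cei and receives the subsidy S; a non-visiting
  platform is fined Fe when low quality is confirmed. Reputation stakes are
  Ie / De.
- Positive regulation costs the government Cg and earns the fine revenue;
  negative regulation risks the superior-government penalty Fg after an
  elderly complaint. High quality yields social welfare Rg; low quality
  causes social loss Dg.
- The elderly pay Cw (online) or Cm (offline) to evaluate, gain Ro from
  good service, lose Do from bad service, and complain with probability β
  at cost Co.
- Detection channels: when neither platform visits nor government
  regulates, all sanctions and compensation are discounted by the complaint
  rate β. Offline evaluation reaches only a fraction γ of the audience, so
  every reputational term is scaled by γ in offline cells.

Expected utilities marginalise the matrix over the opponents' independent
mixing probabilities. The incentive differences

- G(y,z,w) = w(1−γ)(Is+Ds) + zFs + Csl − Csh + Isγ + Dsγ + yIo + (1−y)zIo + (1−y)(1−z)β(Fs+Io)
- H(x,z,w) = w(1−γ)(Ie+De) + Ieγ + Deγ + S − Cei + (1−x)[zFe + (1−z)βFe]
- P(x,y) = (1−x)[Fs + (1−y)Fe − (1−y)β(Fs+Fe−Fg)] − Cg
- Cm − Cw (elderly)

drive the replicator equations dv/dt = v(1−v)·(incentive). The payoff
matrix and the closed-form utility layer are implemented independently and
cross-checked against each other by brute-force expectation in the tests;
the replicator module consumes only the incentive functions, keeping one
source of truth for the algebra.

## Equilibria and stability

Every corner of the cube is a fixed point; in a multi-population replicator
game only strict (pure) Nash equilibria can be asymptotically stable, so
the analysis classifies the 16 corners E1–E16 (E1–E8 on the offline face
w = 0, E9–E16 on the online face w = 1, in the frozen tabulation order).
At a corner the Jacobian is exactly diagonal — each cross-derivative
carries a factor v(1−v) = 0 — with entries (1−2x)G, (1−2y)H, (1−2z)P,
(1−2w)(Cm−Cw). Lyapunov's first method labels a corner ESS when all four
eigenvalues are below −tol (default tol = 1e−9, configurable), unstable
when any exceeds +tol, and indeterminate (non-hyperbolic) otherwise —
never silently resolved.

`table_eigenvalues` retains an independent transcription of the tabulated
symbolic eigenvalue table and is held equal to the Jacobian diagonal on
random parameter sets in the tests. One transcription error in that
table is corrected there: the first eigenvalue of E16(1,1,1,1) must be
−G(1,1,1) = Csh−Csl−Is−Ds−Fs−Io; the printed version carries a spurious
−S term.

**Unconditional instability.** Whether an eigenvalue expression is
sign-definite (like the +Cg entry of the x = 1, z = 1 corners) is decided
by sign-sampling rather than symbolic proof: an eigenvalue is flagged
always-positive when it is positive in every one of ≥1000 random
admissible parameter draws (magnitudes uniform on [0.5, 60], rates in
(0,1), Csh forced above Csl). This avoids a computer-algebra dependency
and reproduces the tabulated sign judgements; it is a statistical
procedure, so a pathologically narrow sign region could in principle be
missed, but every flag here traces to a manifestly positive entry.

## Thresholds and volumes

All critical levels are computed as roots of the affine incentive
functions, evaluated at two points and interpolated exactly — never
re-transcribed from derived formulas. This guarantees the defining
property (substituting the threshold back zeroes the incentive) by
construction, and it resolves a typo in the conventional provider-threshold formula,
whose denominator must be the w-coefficient of G, (1−γ)(Is+Ds).
Degenerate coefficients (e.g. the Fs-coefficient z + (1−y)(1−z)β = 0,
meaning no detection channel exists) raise a dedicated error instead of
returning ±inf.

Strategy volumes integrate the threshold surfaces over the opposing
probability cube: Vx0 = (2a+b)/[2(1−γ)(Is+Ds)] with the fixed platform
share y as an explicit argument (the x-integration of the defining double
integral is a no-op), Vy0 = (2c−d)/[2(1−γ)(Ie+De)] at fixed z, and
Vz1 = 1 − Cg·ln|1+m/Fs|/m with m = Fe−βFs−βFe+βFg and the m → 0 limit
handled as Cg/Fs. The raw pair always sums to 1 but may leave [0,1]
because the integrand is an unclamped surface; both the raw values and
their clamped, probability-interpretable versions are reported. Closed
forms are verified against adaptive quadrature in the tests.

A caveat on reputation monotonicity: the claim that the platform's
positive-visit volume Vy1 rises with Ie and De holds only while the raw
negative-visit volume is a genuine probability (2c − d > −2γ(Ie+De)). At
the baseline set c < 0, so the raw Vy1 sits above 1 and *decreases* toward
1 as reputation grows, while the clamped probability stays pinned at 1.
The tests assert the sign that actually holds in each regime.

## Simulation

The system-dynamics engine advances the replicator field with forward
Euler on the fixed grid t ∈ [0, 3], step 0.0125 (241 points), mirroring a
Vensim-style stock-flow integration; classical RK4 is available for
verification and the two agree to ~1e−2 at the default step on the smooth
baseline field. Post-step clamping to [0,1] is on by default so Euler
overshoot cannot produce invalid probabilities; the unclamped field itself
never points out of the cube, so clamping only absorbs round-off. A
non-finite state aborts with an error naming the step. Runs contain no
randomness and are bit-reproducible.

The initial state is not part of the model specification; the default is
the maximally undecided profile (0.5, 0.5, 0.5, 0.5), always configurable
and recorded in every output. Convergence is detected when a share stays
within tol (default 0.01) of a corner over a trailing window (default 40
grid points), and evolution speed is measured as the first grid time a
share comes within 0.01 of its final corner.

Five sensitivity suites perturb the study conditions: Fs and Io ∈
{0.5×, 1×, 1.5×} baseline; Fe and S likewise; initial w ∈ {0.25, 0.75}
(interpreted as an initial condition — w still evolves — since the
elderly population does reach a stable strategy; a `hold` option freezes
w for the exogenous-share reading); Is, Ds, Ie, De jointly × 0.5 / × 1.5;
β ∈ {0.01, 0.41}. On the default grid these reproduce the expected
qualitative orderings: every strengthened lever weakly accelerates its
player (strictly for Fs, Io, S and reputation; the Fe effect is real but
below grid resolution because it enters only through (1−x)·[z+(1−z)β]·Fe),
a larger initial w accelerates all three other players, and a higher
complaint rate speeds providers toward high quality while slowing the
government's drift to negative regulation.

## Parameters

Monetary quantities are abstract currency units (no empirical calibration
is attempted); α, β, γ are fractions in [0, 1], stored as fractions even
where conventionally quoted as percentages. The baseline set is Rs=100,
Csh=50, Csl=25, Is=20, Ds=22, S=10, Ceo=15, Cei=5, Ie=10, De=12, α=0.10,
β=0.01, γ=0.05, Fs=20, Fe=5, Fg=200, Rg=40, Cg=10, Dg=40, Cm=10, Cw=8,
Io=10, Ro=20, Do=30, Co=5 — chosen so the three inequalities that make the
socially desirable corner attainable hold: Cw−Cm = −2 < 0,
Cei−Ie−De = −17 < 0, Csh−Csl−Is−Ds−Io = −27 < 0. Parameter sets are
immutable; scenario edits always produce validated copies, and config
files must use exactly the canonical field names (unknown keys are errors,
so typos in scenario configs fail loudly).

## Scope and limitations

- The model is deterministic replicator dynamics; no finite-population
  (Moran / Wright–Fisher) noise, and no interior (mixed) equilibrium
  solving — mixed fixed points are never asymptotically stable here.
- Exactly two strategies per player and four players; the payoff matrix is
  hand-coded, not generated.
- Threshold and volume formulas treat the opponents' probabilities as
  exogenous coordinates; they describe incentives, not equilibrium
  selection.
- Corollary-style derivative signs are checked numerically at concrete
  parameter sets, not proven symbolically.
- The simulation reproduces dynamics, not stock-flow diagram artwork
  (no .mdl parsing); only the dynamics are modelled.
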