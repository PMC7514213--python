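# Methods

## Model and causal structure

Time is discrete. One step runs `y_{τ+1} → z_{τ+1} → x_{τ+1} → replication by
e^{k(x_{τ+1}, y_{τ+1})}`: the environment moves first (Markov kernel
`TEF(y′|y)`), each cell then senses (`TS(z′|z, y′)`, memoryless special case
`TS(z′|y′)`), switches phenotype (`TF(x′|x, z′)`), and finally replicates.
No replication occurs at τ = 0; the historical fitness
`K[Xt,Yt] = Σ_{τ=0}^{t-1} k(x_{τ+1}, y_{τ+1})` and the allocation sum
`Kmax[Yt] = Σ_{τ=1}^{t} kmax(y_τ)` both skip the initial pair.

Populations are deterministic given the realized histories (no demographic
noise): with individual sensing the state is a joint `(x, z)` abundance
table, with common sensing an `x` table. Initial abundance is normalized to
total 1 (`N0(x,z) = pS(z|y0) pF(x|z)`, resp. `N0(x) = pF(x|z0)`), so the log
total at time t is the fitness `Ψ` directly.

Kernels are stored row-stochastically (conditioning state → outgoing
distribution); printed matrices in this literature are often the transpose
(columns summing to 1), and the bundled config documents the orientation.
Stochasticity is validated to 1e-9 and violations are hard errors — config
files carry at most ~4 significant digits, so anything worse than 1e-9 is a
genuine mistake, not rounding.

Defaults when a config omits initial laws: `pE` = stationary distribution of
`TEF`; `pS(z0|y0)` = the memoryless sensing kernel; `pF(x0|z0)` = the
memoryless switching kernel. All overridable.

## Numerics

All path weights and abundances live in the log domain with `-inf` for exact
zeros (`0·e^{-inf} ≡ 0`); sums use log-sum-exp. This matters because `e^K`
spans hundreds of orders of magnitude by t ≈ 20. Fitness values are computed
by batched transfer-matrix recursions (one matrix contraction per time step,
vectorized across histories or Monte-Carlo samples), which equal the
exhaustive path sums; the test suite checks agreement with brute-force
enumeration to 1e-10 relative error on random models.

Exhaustive enumerations are guarded at 10^7 entries (override explicitly).
The total fidelity `γ_t = ln Σ_{Yt} PKFS[Yt|Yt]` is linear in the path
weights, so it is evaluated for any horizon by a joint `(x, z)` transfer
matrix that folds the matched environment state in step by step — no
enumeration; enumeration cross-checks it at small t.

Monte-Carlo sampling draws environment and signal histories jointly forward
(`Q[Zt‖Yt] = PS`, the same law as individual sensing) using a counter-based
Philox generator: one uniform block per run, reproducible given (seed, n),
with per-sample rows acting as independent streams. Integral-FR integrands
`e^{-A}` are heavy-tailed, so reports carry the sample maximum and a
variance-based standard error alongside the running mean.

## The decomposition and its pin

`e^{k(x,y)} = e^{kmax(y)} TK(y|x)` is solved as a linear system in
`u_y = e^{-kmax(y)}` (one row-sum equation per phenotype). With more
environments than phenotypes the system is underdetermined — the bundled
model has a one-parameter family — so an explicit pin is required. The
bundled pin is `e^{kmax} = 0.16` in the nutrient-poor state, which forces
`e^{kmax} = 5.12` in both rich states and `TK(poor|·) = 0.5`. `σ`, `γ_t` and
`P_γ` depend on the pin; the fluctuation relations and the combination
`γ_t − ⟨σ⟩ − D[Q‖P_γ]` do not, and the tests assert exactly that.

`PKFS[Yt′|Yt]` — the probability that metabolic resources follow allocation
history `Yt′` when `Yt` is realized — allocates nothing at time 0, so its
time-0 slot is pinned to the realized initial state. This makes `PKFS` a
normalized distribution over allocation histories and leaves the diagonal
(hence `σ`, `γ_t`, and every fluctuation relation) untouched.

## Time-0 bookkeeping in the directed-information relations

The Bayesian causal decomposition factorizes the joint forward law as
`PS[Yt,Zt] = PSB[Yt‖Zt] · PSB[Zt‖Yt−1]`, with the environment-posterior
product carrying an initial factor `p(y0|z0)` and the signal-predictive
product an initial marginal `p(z0) = Σ_{y0} pS(z0|y0) pE(y0)`. The
allocation-through-switching kernel `PK,F[Yt|Zt] = Σ_X PK[Yt‖Xt] PF[Xt‖Zt]`,
by contrast, contains no factor for `y0` at all — nothing ever allocates the
initial environment state. Consequences, which the package reports honestly
rather than glossing over:

* the average identities `⟨Ψ_i⟩ = ⟨Ψ_0⟩ + I + G − Dloss` and
  `⟨Ψ_c⟩ = ⟨Ψ_0⟩ + I − Dloss` are algebraic and hold for **any** initial
  law (residuals < 1e-9 in the tests);
* but the reference measure `PK,F · PSB[Zt‖Yt−1]` has total mass `|Sy|`,
  not 1, when the initial environment is random. The integral relation for
  `Ψ_0 + i + g − Ψ_i` then evaluates to `|Sy|`, `Dloss` is not a proper KL
  divergence (it can be negative — the bundled model shows `Dloss < 0` at
  t = 1), and the bound `⟨Ψ_c⟩ − ⟨Ψ_0⟩ ≤ I` can fail near the optimal
  strategy.

All of these become exact theorems when the initial environment state is
known (`p(y0|z0)` a point mass): the optimal posterior-switching strategy
presumes the current environment is tracked by the phenotype, which at time
0 requires a known starting state. `with_known_initial_environment(model,
label)` conditions a model accordingly; the third integral relation, the
`Dloss = 0` optimality check, and the directed-information bound are
verified on such models (the CLI `reproduce-demo` does this automatically
for the third relation). The sensing-gain relation `⟨e^{−g}⟩ = 1` and the
average identities need no such conditioning. Conversely, the fidelity
relation `⟨e^{−(γ_t−σ)}⟩ = 1` requires the initial law to have **full
support** (γ_t sums over all histories, Q only over its support), so it is
verified on the stationary-start model.

## Optimal strategies

With `|Sx| = |Sy|` (identification by label order unless a bijection is
given), the Bayesian-sequential-inference pair is: delta allocation
`TK*(y|x) = δ_{x,y}` — each phenotype commits everything to its matched
environment and cannot grow elsewhere (off-diagonal log rates are `-inf`,
true zero abundance multiplication) — and switching equal to the Bayesian
posterior of the next environment given the sensed signal and the current
matched state, with `pF*(x0|z0)` the time-0 posterior. `kmax*` keeps the
model's matched-diagonal replication rates. Posterior rows conditioned on
signals that cannot occur from a given state are filled uniformly; they
carry zero forward weight. No numerical optimizer over `(TF, TK)` is
provided: the closed forms and the inequalities they satisfy are the scope.

## What the bundled model does and does not show

The bundled three-state model emulates a population alternating between two
nutrient regimes with occasional famine: specialist phenotypes (7× growth
advantage when matched, near-death in famine), 80%-accurate memoryless
sensing, 95%-faithful memoryless switching, stationary environment start.
It exercises every code path except kernels with memory, which random-model
property tests cover. Passing tests on it (and on random small models)
demonstrate the *identities* and *algorithms*, not biological realism: real
populations have finite size (demographic noise), cell–cell interactions,
carrying capacities, and feedback from population to environment, all
outside this model class by construction.

## Problem sizes used in checks

Exhaustive verifications run at horizons t ≤ 5 (≤ 3^6 environment × 2^6
signal histories jointly); Monte-Carlo runs use t = 20 with 10^5 samples,
where the running average of `e^{−g}` reaches 1 within ~1% (three standard
errors). These sizes make the full suite run in well under a minute while
leaving the large-horizon behavior to the seeded sampler.
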