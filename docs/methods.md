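# Methods

## The plant model

`aerompc` models the aerated biological stage of one treatment line of a
municipal activated-sludge plant as a single continuously stirred tank with
six states (all g/m³):

| state  | meaning                          | typical value |
|--------|----------------------------------|---------------|
| X_COD  | lumped organic substrate (COD)   | ~1            |
| S_O    | dissolved oxygen                 | 0.5–2.5       |
| S_NH   | ammonium nitrogen                | ~0.3          |
| S_NO   | nitrate nitrogen                 | 3–19          |
| X_BH   | heterotrophic biomass            | ~4500         |
| X_BA   | autotrophic (nitrifying) biomass | ~150          |

Each balance is Accumulation = Inflow − Outflow + Reaction.  The reactions
are five Monod-kinetic rates: aerobic heterotrophic growth on COD, anoxic
heterotrophic growth with nitrate as electron acceptor (inhibited by
oxygen through K_OH/(K_OH+S_O)), aerobic autotrophic growth on ammonium,
and first-order decay of both biomasses.  The sole manipulated input is
the oxygen transfer coefficient KLa (1/day) acting through
KLa·(SO_sat − S_O).  The secondary settler is not modelled dynamically;
its effect is the retention factor f_w(1+f_r)/(f_r+f_w) ≈ 0.015 that
scales the hydraulic washout of the particulate states, which is what
lets mixed-liquor biomass sit three orders of magnitude above its influent
concentration.

Kinetic and stoichiometric defaults are the standard ASM1/BSM1 benchmark
values (Yh=0.67, Ya=0.24, μh=4/d, μa=0.5/d, K_COD=10, K_OH=0.2, K_NO=0.5,
K_NH,A=1, K_OA=0.4, bh=0.3/d, ba=0.05/d, i_xb=0.08, i_xp=0.06, f_p=0.08,
η_NOg=0.8, SO_sat=8 g/m³, KLa ∈ [0, 240]/d); everything is overridable
from YAML.  Time is measured in days throughout; the 15-min controller
sample is h = 1/96 d.

**Reactor sizing.** The plant has three parallel identical lines; the
package simulates one line, so the influent flow is divided by three
(`flow_split=1/3`) while concentrations are unchanged.  The lumped reactor
volume defaults to V_o = 4614 m³, the sum of the three aerated tanks of
one line (1929+1276+1409 m³).  Sizing the model on a single tank instead
makes the peak oxygen demand, roughly
(Qin/V_o)·[(1−Yh)·COD_in + 4.57·nitrified N], exceed the maximum aeration
capacity KLa_max·(SO_sat − S_O), and no controller can then hold a DO
band; the lumped-line volume leaves a realistic margin (mean KLa ≈ 135/d
at mean load).

**Default initial state.** Runs start from the plant's own regulated
operating point under mean load with DO held at 2 g/m³, obtained by a
long (120-day) pilot simulation: (X_COD, S_O, S_NH, S_NO, X_BH, X_BA) =
(1, 2, 0.3, 15, 4500, 150) g/m³.  Starting instead from influent-like
concentrations (X_COD ≈ 100, S_NH ≈ 20) triggers a COD burn whose oxygen
demand (~KLa 540/d) exceeds the aeration capacity and tells nothing about
normal operation.

## Exact quasi-LPV embedding

The model's nonlinearities are products of Monod factors and states, so
the dynamics embed exactly — not approximately — in a
linear-parameter-varying form dx/dt = A(σ)x + B(σ)u + Ew with five
scheduling variables:

    σ1 = Qin
    σ2 = X_COD/(K_COD+X_COD) · S_O/(K_OH+S_O)
    σ3 = X_COD/(K_COD+X_COD) · S_NO/(K_NO+S_NO) · K_OH/(K_OH+S_O)
    σ4 = S_NH/(K_NH,A+S_NH) · X_BA/(K_OA+S_O)
    σ5 = S_O

Heterotrophic growth (θ1 = μh·σ2·X_BH, θ2 = μh·η_NOg·σ3·X_BH) is carried
by the X_BH column of A; nitrification (θ3 = μa·σ4·S_O) by the S_O
column; the aeration input enters through b = SO_sat − σ5.  E is the
constant (1/V_o) selector injecting the exogenous loads
w = (Qin·XCOD_in, Qin·SNH_in, Qin·XBH_in) into the X_COD, S_NH and X_BH
rows.  A and B are affine in σ and the zero pattern of A is independent
of σ — both are asserted by tests, and the embedding is verified to
reproduce the nonlinear right-hand side to 1e-9 relative at 1000 random
states including boundary cases.  The soluble rows carry the hydraulic
dilution −σ1/V_o on their diagonal (a requirement of the mass balances;
without those diagonal entries the embedding cannot be exact).

The measured-output map is the constant selector C of (S_O, S_NH, S_NO) —
the concentrations a plant actually instruments; COD and the two biomass
states must be estimated.

## Discretization

`discretize` is the exact zero-order-hold map via the augmented matrix
exponential, with σ frozen over the step.  One caveat drove a second
variant: at realistic loading the substrate state relaxes on a ~2-minute
time constant, so over a 15-minute step a *single* frozen-σ factor
overshoots the self-limiting Monod kinetics badly enough to predict
negative substrate.  `discretize_along` therefore composes `n_substeps`
(default 20, i.e. 45-second) frozen-σ ZOH factors, re-evaluating σ at the
state propagated through the previous factors.  The result is still one
affine one-step map; its error against the true nonlinear flow is below
0.02 g/m³ per state per step at the operating point (versus ~8 g/m³ for a
single frozen step).  The estimator and the controller's one-step
prediction map use the sub-stepped variant; plain `discretize` remains
for analysis and for systems without this stiffness.

## Economic MPC

At each sample the controller minimizes, over the input sequence
u(0..Hp−1) with Hp = 24 (6 h),

    w1·Σ Jeco + w2·Σ Jsmo + w3·Σ ||λ||²  (+ soft effluent box)

subject to the frozen-scheduling prediction model and hard input bounds
0 ≤ u ≤ 240/d.  The pieces:

* **Energy.** Jeco(u) = SO_sat/1800 · V_o · u (kWh/day), the benchmark
  aeration-energy convention; linear in u.
* **DO band.** The dissolved-oxygen state must stay inside a scenario
  band, softened by nonnegative slacks penalized quadratically:
  band_low − λ⁻ ≤ x_SO ≤ band_high + λ⁺.  The optimizer sees the band
  tightened by `band_margin` (default 0.15 g/m³) on each side: with a
  linear energy cost the optimum rides *exactly* on the softened floor
  minus an O(w1/w3) offset, so the back-off keeps the realized DO inside
  the physical band despite prediction error and sensor noise.
* **Smoothing.** Jsmo = Wu·Δu² limits input moves (equipment
  conservation and, as importantly, robustness: large KLa slams excite
  plant–model mismatch).
* **Effluent box.** Upper limits on states/outputs (COD ≤ 125 g/m³ class
  of constraints) are soft with a large penalty so the program never goes
  infeasible under load spikes; violations are logged.  Lower state
  bounds are deliberately *not* imposed on the prediction (the
  long-horizon frozen model drifts the fast substrate state negative by
  construction; penalizing that injects a spurious gradient).

Default weights w1=1, w2=1, w3=1e4, Wu=1.  The large w3 encodes the
operational priority: effluent quality is met regardless of load, energy
is minimized subject to that.  With w3 on the order of 10²–10³ the energy
term wins at low DO and the controller abandons the band — a starvation
trap, because the frozen-σ model evaluated at low S_O and elevated S_NH
vastly overestimates the nitrification oxygen sink and declares the band
unreachable.

**Solution method.** Because each slack is bounded below by a single
affine function of u, the slacks are eliminated analytically
(λ* = max(0, violation)), leaving a smooth convex piecewise-quadratic
function of u over a box.  This is minimized with L-BFGS-B (analytic
gradient, deterministic settings, warm-started from the shifted previous
solution).  The eliminated form has the same minimizer as the explicit
QP; `QPProblem.quadratic_term` still exposes the QP's PSD Hessian block
over (u, λ⁻, λ⁺) and the tests verify solver optimality against a
closed-form Hp=1 stationary point and an Hp=2 brute-force grid oracle.
Line-search aborts at stationary points are accepted when the projected
gradient is below 0.05; anything else falls back to the previously
applied input and is logged.

**Disturbance forecast.** The influent over the horizon is held at the
last measured record by default (`forecast_mode="hold"`); a perfect
forecast mode exists for ablations.

## Moving-horizon estimation

Only (S_O, S_NH, S_NO) are measured.  Over a sliding window of N = 12
steps (3 h) the estimator solves

    min (x̂(−N)−x_prior)ᵀPo(x̂(−N)−x_prior) + Σ εᵢᵀQεᵢ + Σ sᵢᵀRsᵢ
    s.t. x̂(i+1) = Ad_i x̂(i) + Bd_i u(i) + Ed_i w(i) + ε(i)
         y(i) = C x̂(i) + s(i),   0 ≤ x̂ ≤ x_box

a box-constrained linear least-squares solved exactly with BVLS.  The
current estimate is the last element of the window sequence; on advance,
the arrival prior moves to the previous window's smoothed estimate at the
new window start.  Before N samples exist, a growing-window problem is
solved.

Weights are read as inverse variances.  R = 400·I matches ~0.05 g/m³
sensor noise.  Q is per-state: loose on the model-error-prone substrate
and oxygen rows, stiff on ammonium/nitrate, very stiff on the biomass
rows whose true motion is a few g/m³ per step.  Po is firm on the biomass
states: the oxygen-uptake data identify only products of Monod factors
and biomass, so the individual factors must be pinned by continuity —
with a loose anchor the optimizer trades thousands of g/m³ of biomass
against sub-0.5 g/m³ measurement residuals, and X_BA in particular is
numerically unobservable whenever nitrification is nitrogen-limited
(S_NH near zero, its usual operating condition).

The window matrices are evaluated along the previously estimated
trajectory and the solve is iterated (`n_iter=2`) with matrices rebuilt
along the fresh estimate, relaxed halfway per iteration (plain successive
substitution overshoots near the Monod half-saturation).  At the
solution, matrices and estimate are mutually consistent; because the
embedding is exact, the true trajectory is a fixed point of this
iteration, and with noise-free data the window optimum recovers it
exactly (asserted by tests).

Measured recovery quality (pilot, 1-day trajectory, 5 % sensor noise, 20
seeds): worst time-averaged relative error of the unmeasured states 4.1 %
(X_COD ≈ 3 %, X_BH ≈ 0.1 %, X_BA ≈ 0.04 %); the acceptance tests assert
the pre-registered 10 % tolerance.

## Synthetic influent

The generator emulates the diurnal pattern of a medium-size municipal
plant: each channel (flow 10,000–35,000 m³/d; COD 400–650 mg/L; total
nitrogen 40–65 mg/L, of which 70 % enters as ammonium; influent
heterotrophs 30 g/m³ mean) follows a cosine with its peak at 10:30 by
default, an optional second evening harmonic, and truncated (±3σ)
multiplicative Gaussian noise (5 % default), clipped back into the
configured range so bound containment holds record by record.  A fixed
seed gives bitwise-identical series.  BOD bounds are carried in the
config for completeness but unused (BOD is not a state of the reduced
model).

What the generator does *not* emulate: rain and storm events, weekday /
weekend structure, temperature, composition correlations between
channels, and sensor-level artifacts.  Closed-loop results on this
influent therefore demonstrate disturbance rejection of smooth diurnal
loading, not robustness to storm flows.

## Closed loop and scenarios

Per 15-min sample: read noisy outputs → MHE update → build the one-step
prediction model at the estimate → solve the economic MPC → apply the
first input to the nonlinear plant (integrated with LSODA between
samples, with a nonnegativity clip guarding tiny tolerance-level
undershoots).  Two standard scenarios: band (1.5, 2.5) mg/L and band
(0.5, 1.2) mg/L.  Summary metrics exclude the first 12 h as start-up
transient.  Nitrate is monitored against the effluent limit but not
actively controlled — the reduced model exposes only KLa — and total
nitrogen is proxied as S_NH + S_NO (the model carries no organic-N
state), a documented limitation.  In the low-DO scenario the anoxic
correction factor K_OH/(K_OH+S_O) triples, denitrification strengthens,
and effluent nitrate settles around 3–5 mg/L versus 14–19 mg/L in the
high band; aeration energy is correspondingly ~20 % lower.

Problem sizes used by the shipped experiments: 7-day runs at 15-min
sampling (672 control steps, each one MHE solve of 78 variables and one
MPC solve of 24 variables), about 30 s per scenario on one CPU; the test
suite uses 0.25–1-day runs for structural checks and the full 7-day runs
for the acceptance properties.

## Known limitations

* Single lumped aerated reactor: no anoxic-zone dynamics, no settler
  dynamics, no inter-tank gradients; denitrification happens only through
  the low-DO correction term.
* Frozen-scheduling prediction: the controller's Hp-step model uses one
  LTI map per solve; its long-horizon predictions of the fast substrate
  state are qualitative only (the DO row, which the controller acts on,
  is accurate near the operating point).
* No formal stability or recursive-feasibility certificate; robustness is
  demonstrated empirically over seeds.
* Weights are hand-set defaults, not the outcome of a formal multiobjective
  tuning; they are config inputs.
* The nitrifier estimate rests on continuity rather than data whenever
  ammonium is near zero; a sustained, unmodelled X_BA disturbance (e.g.,
  toxic shock) would be tracked only slowly.
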