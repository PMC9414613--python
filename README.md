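# aerompc

Economic model predictive control of the aeration system of an
activated-sludge wastewater treatment plant, in the quasi-LPV framework,
with moving-horizon estimation of the unmeasured biomass and substrate
states.

Aeration is 60–80 % of the energy bill of a biological treatment plant,
yet dissolved oxygen (DO) must stay high enough to sustain COD removal
and nitrification and low enough to avoid waste and poor sludge settling.
`aerompc` is for control engineers and researchers who want a complete,
reproducible sandbox for this problem: a reduced six-state
activated-sludge reactor model, an exact quasi-linear-parameter-varying
(qLPV) embedding that turns the economic MPC into a convex program, a
moving-horizon estimator (MHE) for the states no plant measures, a
seeded diurnal influent generator, and a closed-loop scenario runner.

## The model and the controller

Reduced reactor model (states in g/m³, rates in 1/day, mass balances
`Accumulation = Inflow − Outflow + Reaction` with Monod kinetics):

    x = (X_COD, S_O, S_NH, S_NO, X_BH, X_BA),    u = KLa

Oxygen dynamics, for example:

    dS_O/dt = (Yh−1)/Yh·θ1 + (Ya−4.57)/Ya·θ3 − (Qin/V_o)·S_O
              + KLa·(SO_sat − S_O)

where θ1 is aerobic heterotrophic growth and θ3 nitrification.  Because
every nonlinearity is a Monod-factor product, the dynamics embed exactly
in dx/dt = A(σ)x + B(σ)u + Ew with scheduling vector σ(x, Qin) — linear
in state space, nonlinear in the parameter space.

At each 15-min sample the controller solves the convex program

    min_{u, λ}  w1 Σ Jeco(u) + w2 Σ Wu·Δu² + w3 Σ ||λ||²
    s.t.        x(i+1) = Ad x(i) + Bd u(i) + Ed w(i)
                band_lo − λ⁻ ≤ x_SO(i) ≤ band_hi + λ⁺,   λ ≥ 0
                0 ≤ u(i) ≤ KLa_max

with the economic stage cost Jeco = SO_sat/1800 · V_o · KLa (kWh/day) and
applies the first input of the optimal sequence.  The MHE solves the dual
problem over a sliding 3-h window — weighted least squares on process and
measurement residuals under the same discretized qLPV model, with only
(S_O, S_NH, S_NO) measured — to supply the state estimate the scheduling
needs.  See `docs/methods.md` for the full formulation, weight rationale
and limitations.

## Worked example

Run the low-DO scenario (band 0.5–1.2 mg/L) for two days on synthetic
diurnal influent:

```python
from aerompc import scenario2, run_scenario

rep = run_scenario(scenario2(duration=2.0, seed=1))
s = rep.summary
print(f"max DO (post-transient): {s['max_S_O_post']:.3f} g/m3")
print(f"min DO (post-transient): {s['min_S_O_post']:.3f} g/m3")
print(f"band compliance:         {s['band_fraction_post']:.3f}")
print(f"aeration energy:         {s['total_energy_kwh']:.0f} kWh")
print(f"max effluent nitrate:    {s['max_S_NO_post']:.3f} g/m3")
print(f"max effluent COD:        {s['max_X_COD_post']:.3f} g/m3")
```

prints

```
max DO (post-transient): 0.630 g/m3
min DO (post-transient): 0.530 g/m3
band compliance:         1.000
aeration energy:         4376 kWh
max effluent nitrate:    5.157 g/m3
max effluent COD:        1.337 g/m3
```

The DO rides just above the lower band edge (the economic optimum: less
DO, less energy), every post-warm-up sample is inside the band, nitrate
stays well under the 10 g/m³-class effluent limits because the low DO
strengthens denitrification, and effluent COD is far below the 125 g/m³
standard.  Running `scenario1` (band 1.5–2.5 mg/L) on the same influent
uses about 25 % more energy — the price of the higher oxygen level.

The same is available from the shell:

```
aerompc run --scenario 2 --seed 1 --out results/
aerompc gen-influent --duration 7 --seed 1 --out influent.csv
aerompc simulate --influent-csv influent.csv --u-kla 120 --out openloop.csv
aerompc estimate --trajectory-csv results/scenario2_trajectory.csv \
                 --influent-csv influent.csv --out estimates.csv
```

`run` writes the trajectory CSV, a summary JSON and diagnostic plots
(DO with its band, aeration profile, nitrogen species, MHE estimates vs
truth).

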