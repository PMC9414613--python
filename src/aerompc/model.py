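"""Nonlinear reduced activated-sludge plant model.

Six-state mass-balance model of a lumped aerated reactor
(Accumulation = Inflow - Outflow + Reaction) with Monod kinetics:

    state x = (X_COD, S_O, S_NH, S_NO, X_BH, X_BA)   [g/m^3]

* X_COD -- chemical oxygen demand (soluble + particulate organics lumped)
* S_O   -- dissolved oxygen
* S_NH  -- ammonium nitrogen
* S_NO  -- nitrate nitrogen
* X_BH  -- heterotrophic biomass
* X_BA  -- autotrophic (nitrifying) biomass

The single manipulated input is the oxygen transfer coefficient KLa(t)
entering through the aeration term KLa*(SO_sat - S_O).  Influent carries
COD, ammonium and heterotrophic biomass; influent oxygen, nitrate and
autotrophs are zero by assumption.  Biomass washout is attenuated by the
settler recycle (see :attr:`PlantParameters.washout_ratio`).

This module is the ground truth for the quasi-LPV embedding in
:mod:`aerompc.qlpv` and serves as the continuous plant in closed loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import PlantParameters

logger = logging.getLogger(__name__)

STATE_NAMES = ("X_COD", "S_O", "S_NH", "S_NO", "X_BH", "X_BA")
NX = 6

# indices into the state vector
IX_COD, IX_SO, IX_SNH, IX_SNO, IX_XBH, IX_XBA = range(6)


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.6f} d)")
        self.t_fail = t_fail


@dataclass
class PlantState:
    """Concentration state of the reactor at one instant (g/m^3, t in days)."""

    X_COD: float
    S_O: float
    S_NH: float
    S_NO: float
    X_BH: float
    X_BA: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.X_COD, self.S_O, self.S_NH,
                         self.S_NO, self.X_BH, self.X_BA], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray, t: float = 0.0) -> "PlantState":
        x = np.asarray(x, dtype=float)
        if x.shape != (NX,):
            raise ValueError(f"state vector must have shape ({NX},)")
        return cls(*x, t=t)

    def validate(self) -> None:
        if np.any(self.as_array() < 0):
            raise ValueError(f"negative concentration in state: {self}")


@dataclass(frozen=True)
class InfluentRecord:
    """Influent flow and concentrations at one time step.

    SO_in = SNO_in = XBA_in = 0 by model assumption, so only Qin, COD,
    ammonium and heterotrophic biomass are carried.
    """

    t: float            # days
    Qin: float          # m^3/day
    XCOD_in: float      # g/m^3
    SNH_in: float       # g/m^3
    XBH_in: float       # g/m^3

    def __post_init__(self) -> None:
        if self.Qin <= 0:
            raise ValueError("influent flow Qin must be strictly positive")
        if min(self.XCOD_in, self.SNH_in, self.XBH_in) < 0:
            raise ValueError("influent concentrations must be nonnegative")

    def scaled(self, flow_fraction: float) -> "InfluentRecord":
        """Influent seen by one of several identical parallel lines."""
        return InfluentRecord(self.t, self.Qin * flow_fraction,
                              self.XCOD_in, self.SNH_in, self.XBH_in)

    def exogenous(self) -> np.ndarray:
        """Exogenous input w = (Qin*XCOD_in, Qin*SNH_in, Qin*XBH_in)."""
        return self.Qin * np.array([self.XCOD_in, self.SNH_in, self.XBH_in])


@dataclass(frozen=True)
class ReactionRates:
    """The five Monod reaction rates theta_1..theta_5 (g/m^3/day)."""

    theta1: float  # aerobic heterotrophic growth
    theta2: float  # anoxic heterotrophic growth (denitrification)
    theta3: float  # autotrophic growth (nitrification)
    theta4: float  # heterotroph decay
    theta5: float  # autotroph decay

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3,
                         self.theta4, self.theta5])


@dataclass(frozen=True)
class TransportTerms:
    """Hydraulic inflow/washout and aeration terms vartheta_1..6 (g/m^3/day)."""

    vartheta1: float
    vartheta2: float
    vartheta3: float
    vartheta4: float
    vartheta5: float
    vartheta6: float

    def as_array(self) -> np.ndarray:
        return np.array([self.vartheta1, self.vartheta2, self.vartheta3,
                         self.vartheta4, self.vartheta5, self.vartheta6])


def reaction_rates(state: PlantState, params: PlantParameters) -> ReactionRates:
    """Evaluate the five Monod reaction rates at ``state``.

    theta1 : aerobic growth of heterotrophs on COD,
    theta2 : anoxic growth of heterotrophs on COD with nitrate as electron
             acceptor (inhibited by oxygen via K_OH/(K_OH+S_O)),
    theta3 : aerobic growth of autotrophs on ammonium,
    theta4, theta5 : first-order biomass decay.
    """
    state.validate()
    x = state.as_array()
    return ReactionRates(*_reaction_rates_array(x, params))


def _reaction_rates_array(x: np.ndarray, p: PlantParameters) -> np.ndarray:
    cod, so, snh, sno, xbh, xba = x
    f_cod = cod / (p.K_COD + cod)
    f_oh = so / (p.K_OH + so)
    f_no = sno / (p.K_NO + sno)
    f_nh = snh / (p.K_NHA + snh)
    f_oa = so / (p.K_OA + so)
    f_anox = p.K_OH / (p.K_OH + so)
    theta1 = p.mu_h * f_cod * f_oh * xbh
    theta2 = p.mu_h * p.eta_NOg * f_cod * f_no * f_anox * xbh
    theta3 = p.mu_a * f_nh * f_oa * xba
    theta4 = p.b_h * xbh
    theta5 = p.b_a * xba
    return np.array([theta1, theta2, theta3, theta4, theta5])


def transport_terms(state: PlantState, influent: InfluentRecord,
                    u_KLa: float, params: PlantParameters) -> TransportTerms:
    """Hydraulic and aeration contributions to each state derivative.

    Soluble states are diluted at the rate Qin/V_o; particulate biomass is
    retained by the settler and washes out at the reduced rate
    (Qin/V_o)*washout_ratio.  vartheta2 carries the aeration input
    KLa*(SO_sat - S_O).
    """
    return TransportTerms(*_transport_terms_array(
        state.as_array(), influent, u_KLa, params))


def _transport_terms_array(x: np.ndarray, influent: InfluentRecord,
                           u_KLa: float, p: PlantParameters) -> np.ndarray:
    cod, so, snh, sno, xbh, xba = x
    d = influent.Qin / p.V_o          # dilution rate, 1/day
    rho = p.washout_ratio
    return np.array([
        d * (influent.XCOD_in - cod),
        d * (-so) + u_KLa * (p.SO_sat - so),
        d * (influent.SNH_in - snh),
        d * (-sno),
        d * (influent.XBH_in - rho * xbh),
        d * (-rho * xba),
    ])


def rhs(state: PlantState, influent: InfluentRecord, u_KLa: float,
        params: PlantParameters) -> np.ndarray:
    """Time derivative of the six states (g/m^3/day)."""
    state.validate()
    return rhs_array(state.as_array(), influent, u_KLa, params)


def rhs_array(x: np.ndarray, influent: InfluentRecord, u_KLa: float,
              p: PlantParameters) -> np.ndarray:
    """Vectorized right-hand side on a bare state array (no validation)."""
    th1, th2, th3, th4, th5 = _reaction_rates_array(x, p)
    vt = _transport_terms_array(x, influent, u_KLa, p)
    decay_cod = (1.0 - p.f_p) * (th4 + th5)
    decay_n = (p.i_xb - p.f_p * p.i_xp) * (th4 + th5)
    dx = np.array([
        -(th1 + th2) / p.Yh + decay_cod,
        (p.Yh - 1.0) / p.Yh * th1 + (p.Ya - 4.57) / p.Ya * th3,
        -p.i_xb * (th1 + th2) - (p.i_xb + 1.0 / p.Ya) * th3 + decay_n,
        -(1.0 - p.Yh) / (2.86 * p.Yh) * th2 + th3 / p.Ya,
        th1 + th2 - th4,
        th3 - th5,
    ])
    return dx + vt


def integrate(state0: PlantState, influent_fn, control_fn,
              t_span: tuple[float, float], params: PlantParameters,
              t_eval: np.ndarray | None = None,
              rtol: float = 1e-7, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the plant over ``t_span`` under time-varying inputs.

    Parameters
    ----------
    influent_fn : callable t -> InfluentRecord
    control_fn : callable t -> KLa value (1/day)
    t_eval : sampling grid; defaults to the span endpoints.

    Returns ``(t, X)`` with X of shape (len(t), 6).  A nonnegativity
    safeguard clips tiny negative excursions (stiff Monod terms can
    undershoot zero by integrator tolerance); clips are logged.
    """
    t0, tf = float(t_span[0]), float(t_span[1])
    if tf < t0:
        raise ValueError("t_span must be increasing")
    x0 = state0.as_array()
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if t_eval is None:
        t_eval = np.array([t0, tf])
    if tf == t0:
        return np.asarray(t_eval, float), np.tile(x0, (len(t_eval), 1))

    def f(t, x):
        # evaluate kinetics on the clipped state so rates stay physical
        return rhs_array(np.maximum(x, 0.0), influent_fn(t),
                         control_fn(t), params)

    sol = solve_ivp(f, (t0, tf), x0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", sol.t[-1])
    X = sol.y.T
    n_neg = int(np.sum(X < 0))
    if n_neg:
        logger.debug("clipped %d negative integrator values to 0", n_neg)
        X = np.maximum(X, 0.0)
    return sol.t, X
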