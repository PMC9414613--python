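"""Exact quasi-LPV embedding of the reduced activated-sludge model.

The nonlinearities of the reduced model are Monod products of the states;
hiding them in five scheduling variables sigma(x, Qin) yields a state-space
model

    dx/dt = A(sigma) x + B(sigma) u + E w

that reproduces the nonlinear right-hand side *identically* when evaluated
at the true state (exact embedding, not a linearization).  A(sigma) and
B(sigma) are affine in sigma; E is constant.  The scheduling variables are

    sigma1 = Qin
    sigma2 = XCOD/(K_COD+XCOD) * S_O/(K_OH+S_O)        (aerobic factor)
    sigma3 = XCOD/(K_COD+XCOD) * SNO/(K_NO+SNO)
             * K_OH/(K_OH+S_O)                          (anoxic factor)
    sigma4 = SNH/(K_NHA+SNH) * X_BA/(K_OA+S_O)          (nitrification)
    sigma5 = S_O

so that theta1 = mu_h*sigma2*X_BH, theta2 = mu_h*eta_NOg*sigma3*X_BH and
theta3 = mu_a*sigma4*S_O: heterotrophic growth is carried by the X_BH
column of A and nitrification by the S_O column.

The measured-output map is the constant selector C of (S_O, S_NH, S_NO);
these are the concentrations instrumented in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .model import NX, IX_SO, IX_SNH, IX_SNO, InfluentRecord, PlantState
from .params import PlantParameters

NW = 3  # exogenous inputs (Qin*XCOD_in, Qin*SNH_in, Qin*XBH_in)
NY = 3  # measured outputs (S_O, S_NH, S_NO)

#: constant output selector: y = C x = (S_O, S_NH, S_NO)
C_OUTPUT = np.zeros((NY, NX))
C_OUTPUT[0, IX_SO] = 1.0
C_OUTPUT[1, IX_SNH] = 1.0
C_OUTPUT[2, IX_SNO] = 1.0


@dataclass(frozen=True)
class SchedulingVector:
    sigma1: float  # m^3/day
    sigma2: float  # dimensionless Monod product
    sigma3: float  # dimensionless Monod product
    sigma4: float  # g/m^3 per (g/m^3) -- X_BA-weighted Monod quotient
    sigma5: float  # g/m^3 (= S_O)

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2, self.sigma3,
                         self.sigma4, self.sigma5])


@dataclass
class LPVMatrices:
    """The (A, B, E) triple at one scheduling point, plus ZOH discretization.

    Continuous-time A (1/day), B (g/m^3 per unit KLa), E (1/m^3 selector);
    after :func:`discretize`, Ad/Bd/Ed hold the zero-order-hold counterparts
    for step ``h`` (days).
    """

    A: np.ndarray
    B: np.ndarray
    E: np.ndarray
    Ad: np.ndarray | None = None
    Bd: np.ndarray | None = None
    Ed: np.ndarray | None = None
    h: float | None = None

    def save_npz(self, path) -> None:
        """Dump the triple (and discretization, if present) for debugging."""
        data = {"A": self.A, "B": self.B, "E": self.E}
        if self.Ad is not None:
            data.update(Ad=self.Ad, Bd=self.Bd, Ed=self.Ed,
                        h=np.asarray(self.h))
        np.savez(path, **data)


def scheduling_vector(state: PlantState | np.ndarray,
                      influent: InfluentRecord,
                      params: PlantParameters) -> SchedulingVector:
    """Evaluate sigma at a (nonnegative) state and influent record."""
    x = state.as_array() if isinstance(state, PlantState) else np.asarray(state, float)
    if np.any(x < 0):
        raise ValueError("scheduling requires a nonnegative state")
    cod, so, snh, sno, _, xba = x
    p = params
    f_cod = cod / (p.K_COD + cod)
    return SchedulingVector(
        sigma1=influent.Qin,
        sigma2=f_cod * so / (p.K_OH + so),
        sigma3=f_cod * sno / (p.K_NO + sno) * p.K_OH / (p.K_OH + so),
        sigma4=snh / (p.K_NHA + snh) * xba / (p.K_OA + so),
        sigma5=so,
    )


def build_matrices(sigma: SchedulingVector,
                   params: PlantParameters) -> LPVMatrices:
    """Assemble the continuous-time (A(sigma), B(sigma), E) triple.

    Every entry is affine in sigma; the zero pattern is independent of
    sigma.  The hydraulic dilution sigma1/V_o appears on the diagonal of
    all soluble rows; biomass rows carry the settler-attenuated washout.
    """
    p = params
    s1, s2, s3, s4, s5 = sigma.as_array()
    d = s1 / p.V_o                     # dilution rate, 1/day
    rho = p.washout_ratio
    growth_h = p.mu_h * (s2 + p.eta_NOg * s3)   # specific heterotroph growth

    A = np.zeros((NX, NX))
    # X_COD row: substrate uptake by X_BH, release by decay of both biomasses
    A[0, 0] = -d
    A[0, 4] = -growth_h / p.Yh + (1.0 - p.f_p) * p.b_h
    A[0, 5] = (1.0 - p.f_p) * p.b_a
    # S_O row: dilution + autotroph uptake (via S_O column), heterotroph uptake
    A[1, 1] = -d - (4.57 - p.Ya) / p.Ya * p.mu_a * s4
    A[1, 4] = (p.Yh - 1.0) / p.Yh * p.mu_h * s2
    # S_NH row
    A[2, 1] = -(p.i_xb + 1.0 / p.Ya) * p.mu_a * s4
    A[2, 2] = -d
    A[2, 4] = -p.i_xb * growth_h + (p.i_xb - p.f_p * p.i_xp) * p.b_h
    A[2, 5] = (p.i_xb - p.f_p * p.i_xp) * p.b_a
    # S_NO row
    A[3, 1] = p.mu_a * s4 / p.Ya
    A[3, 3] = -d
    A[3, 4] = -(1.0 - p.Yh) / (2.86 * p.Yh) * p.mu_h * p.eta_NOg * s3
    # X_BH row
    A[4, 4] = growth_h - p.b_h - d * rho
    # X_BA row
    A[5, 1] = p.mu_a * s4
    A[5, 5] = -p.b_a - d * rho

    B = np.zeros((NX, 1))
    B[1, 0] = p.SO_sat - s5            # aeration driving force

    E = np.zeros((NX, NW))
    E[0, 0] = 1.0 / p.V_o
    E[2, 1] = 1.0 / p.V_o
    E[4, 2] = 1.0 / p.V_o
    return LPVMatrices(A=A, B=B, E=E)


def discretize(mats: LPVMatrices, h: float) -> LPVMatrices:
    """Exact zero-order-hold discretization with frozen scheduling.

    Uses the augmented matrix exponential

        expm([[A, [B E]], [0, 0]] * h) = [[Ad, [Bd Ed]], [0, I]]

    which is exact for constant (sigma, u, w) over the step.
    """
    if h <= 0:
        raise ValueError("discretization step h must be positive")
    BE = np.hstack([mats.B, mats.E])
    if not (np.all(np.isfinite(mats.A)) and np.all(np.isfinite(BE))):
        raise ValueError("non-finite entries in LPV matrices")
    n, m = NX, BE.shape[1]
    M = np.zeros((n + m, n + m))
    M[:n, :n] = mats.A
    M[:n, n:] = BE
    Phi = expm(M * h)
    Ad = Phi[:n, :n]
    Bd = Phi[:n, n:n + 1]
    Ed = Phi[:n, n + 1:]
    return LPVMatrices(A=mats.A, B=mats.B, E=mats.E,
                       Ad=Ad, Bd=Bd, Ed=Ed, h=h)


def lpv_rhs(mats: LPVMatrices, x: np.ndarray, u: float,
            w: np.ndarray) -> np.ndarray:
    """Evaluate A x + B u + E w (continuous time)."""
    return mats.A @ x + mats.B[:, 0] * u + mats.E @ w


def discretize_along(x0: np.ndarray, influent: InfluentRecord, u: float,
                     h: float, n_substeps: int,
                     params: PlantParameters) -> LPVMatrices:
    """Sub-stepped ZOH discretization with scheduling updated en route.

    The substrate state relaxes within minutes, far faster than a 15-min
    sample, so a single frozen-scheduling step badly overshoots its
    self-limiting Monod kinetics.  This variant splits the interval into
    ``n_substeps`` frozen-scheduling ZOH factors, re-evaluating sigma at
    the state propagated through the previous factors, and composes them:

        Ad = Ad_m ... Ad_1,   Bd = sum_j (Ad_m ... Ad_{j+1}) Bd_j

    (same for Ed).  The result is still an affine one-step map consistent
    with the time-varying LPV model; it converges to the nonlinear flow
    as n_substeps grows.
    """
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")
    hs = h / n_substeps
    Ad = np.eye(NX)
    Bd = np.zeros((NX, 1))
    Ed = np.zeros((NX, NW))
    x = np.asarray(x0, dtype=float).copy()
    w = influent.exogenous()
    A_last = B_last = E_last = None
    for _ in range(n_substeps):
        mats = discretize(build_matrices(
            scheduling_vector(np.maximum(x, 0.0), influent, params), params),
            hs)
        Ad = mats.Ad @ Ad
        Bd = mats.Ad @ Bd + mats.Bd
        Ed = mats.Ad @ Ed + mats.Ed
        x = mats.Ad @ x + mats.Bd[:, 0] * u + mats.Ed @ w
        A_last, B_last, E_last = mats.A, mats.B, mats.E
    return LPVMatrices(A=A_last, B=B_last, E=E_last,
                       Ad=Ad, Bd=Bd, Ed=Ed, h=h)
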