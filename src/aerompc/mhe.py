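"""Moving-horizon estimation of the full six-state vector.

Only (S_O, S_NH, S_NO) are measured; COD and the two biomass states must
be reconstructed both for feedback and to evaluate the scheduling
variables of the quasi-LPV model.  Over a sliding window of N steps the
estimator solves the constrained least-squares program

    min  (x(-N) - x_prior)' Po (x(-N) - x_prior)
         + sum_i eps_i' Q eps_i + sum_i s_i' R s_i
    s.t. x(i+1) = Ad_i x(i) + Bd_i u(i) + Ed_i w(i) + eps_i
         y(i) = C x(i) + s_i
         0 <= x(i) <= x_box

where the discretized LPV matrices inside the window are evaluated along
the previously estimated trajectory (scheduling bootstrap).  Substituting
the residual definitions turns this into a box-constrained linear
least-squares in the stacked state trajectory, solved exactly with
scipy.optimize.lsq_linear (BVLS).  The last element of the estimated
sequence is the state estimate handed to the controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky
from scipy.optimize import lsq_linear

from .model import NX, IX_SO, IX_SNH, IX_SNO, InfluentRecord
from .params import PlantParameters
from .qlpv import C_OUTPUT, NY, LPVMatrices, discretize_along


@dataclass
class MHEConfig:
    """Window length, weights and state box of the estimator.

    N = 12 steps at 15-min sampling is a 3-h window: long enough to make
    the slow biomass states visible in the measured outputs, short enough
    for the per-interval scheduling matrices to remain accurate.

    The weights follow an inverse-variance reading.  R = 400 I matches a
    sensor noise of ~0.05 g/m^3.  Q entries are 1/sd^2 of the per-step
    process residual each state can plausibly accumulate: loose on the
    fast, model-error-prone substrate and oxygen rows, stiff on ammonium
    and nitrate (well modelled) and very stiff on the slow biomass states
    so their estimates are carried by continuity rather than by noise.
    Po anchors the window start to the propagated (smoothed-arrival)
    prior; it is read as 1/sd^2 of how far each state may move per window
    relative to that prior.  The biomass anchors are deliberately firm:
    X_BH and X_BA change by only a few g/m^3 per window in reality, and a
    loose anchor would let the optimizer trade large biomass excursions
    against small measurement residuals (the oxygen-uptake data only
    identifies Monod-factor x biomass products, so the individual factors
    must be pinned by continuity).  X_BA in particular is nearly
    unobservable when nitrification is nitrogen-limited (ammonium close
    to zero).

    ``n_iter`` re-linearizations per sample: the window is re-solved with
    LPV matrices rebuilt along the freshly estimated trajectory, so the
    scheduling and the estimate become mutually consistent (iterated MHE).
    """

    N: int = 12
    h: float = 1.0 / 96.0
    n_iter: int = 2
    n_substeps: int = 20
    Q: np.ndarray = field(default_factory=lambda: np.diag(
        [1.0, 1.0, 100.0, 100.0, 0.25, 400.0]))
    R: np.ndarray = field(default_factory=lambda: 400.0 * np.eye(NY))
    Po: np.ndarray = field(default_factory=lambda: np.diag(
        [4e-2, 1.0, 1e-2, 4e-2, 1e-2, 1.0]))
    # physical state box: nonnegativity plus ~10x typical operating values
    x_max: tuple = (1000.0, 20.0, 200.0, 200.0, 40000.0, 2000.0)
    # initial guesses for the unmeasured states (X_COD, X_BH, X_BA)
    x0_guess: tuple = (1.0, 2.0, 0.3, 15.0, 4500.0, 150.0)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.Po = np.asarray(self.Po, dtype=float)
        for name, M, strict in (("Q", self.Q, False), ("R", self.R, True),
                                ("Po", self.Po, False)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            ev = np.linalg.eigvalsh(M)
            if strict and ev.min() <= 0:
                raise ValueError("R must be positive definite")
            if not strict and ev.min() < -1e-12:
                raise ValueError(f"{name} must be positive semidefinite")
        if self.N < 1:
            raise ValueError("window length N must be >= 1")


@dataclass
class EstimationWindow:
    """One fully populated sliding window (N dynamic steps, N+1 nodes)."""

    N: int
    t_hist: list           # N+1 time stamps
    u_hist: list           # N applied inputs
    y_hist: list           # N+1 measurement 3-vectors
    w_hist: list           # N exogenous 3-vectors
    mat_hist: list         # N discretized LPVMatrices
    x_prior: np.ndarray
    Po: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        if not (len(self.u_hist) == len(self.w_hist)
                == len(self.mat_hist) == self.N
                and len(self.y_hist) == len(self.t_hist) == self.N + 1):
            raise ValueError("window histories are not time-aligned")


@dataclass
class EstimateResult:
    x_hat_seq: np.ndarray   # (N+1, NX)
    x_hat_now: np.ndarray   # (NX,)
    eps_seq: np.ndarray     # (N, NX) process residuals
    s_seq: np.ndarray       # (N+1, NY) measurement residuals
    objective: float


def _sqrt_weight(M: np.ndarray) -> np.ndarray:
    """Upper-Cholesky factor of a PSD weight (eigen fallback if singular)."""
    try:
        return cholesky(M, lower=False)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T


def estimate(window: EstimationWindow,
             bounds: tuple[np.ndarray, np.ndarray] | None = None) -> EstimateResult:
    """Solve the window program; global optimum of the convex QP.

    ``bounds`` is the state box (lo, hi) applied to every node; defaults
    to nonnegativity only.
    """
    N = window.N
    nz = (N + 1) * NX
    Lq = _sqrt_weight(window.Q)
    Lr = _sqrt_weight(window.R)
    Lp = _sqrt_weight(window.Po)

    rows = NX + N * NX + (N + 1) * NY
    A = np.zeros((rows, nz))
    b = np.zeros(rows)
    r = 0
    # arrival cost
    A[r:r + NX, 0:NX] = Lp
    b[r:r + NX] = Lp @ window.x_prior
    r += NX
    # dynamics residuals
    for i, mats in enumerate(window.mat_hist):
        ci, ni = i * NX, (i + 1) * NX
        A[r:r + NX, ni:ni + NX] = Lq
        A[r:r + NX, ci:ci + NX] = -Lq @ mats.Ad
        b[r:r + NX] = Lq @ (mats.Bd[:, 0] * window.u_hist[i]
                            + mats.Ed @ np.asarray(window.w_hist[i]))
        r += NX
    # measurement residuals
    for i, y in enumerate(window.y_hist):
        ci = i * NX
        A[r:r + NY, ci:ci + NX] = Lr @ C_OUTPUT
        b[r:r + NY] = Lr @ np.asarray(y, dtype=float)
        r += NY

    if bounds is None:
        lo = np.zeros(nz)
        hi = np.full(nz, np.inf)
    else:
        lo = np.tile(np.asarray(bounds[0], dtype=float), N + 1)
        hi = np.tile(np.asarray(bounds[1], dtype=float), N + 1)

    res = lsq_linear(A, b, bounds=(lo, hi), method="bvls", tol=1e-12)
    z = res.x
    X = z.reshape(N + 1, NX)
    eps = np.empty((N, NX))
    for i, mats in enumerate(window.mat_hist):
        eps[i] = X[i + 1] - (mats.Ad @ X[i] + mats.Bd[:, 0] * window.u_hist[i]
                             + mats.Ed @ np.asarray(window.w_hist[i]))
    s = np.asarray(window.y_hist) - X @ C_OUTPUT.T
    obj = float((X[0] - window.x_prior) @ window.Po @ (X[0] - window.x_prior)
                + sum(e @ window.Q @ e for e in eps)
                + sum(si @ window.R @ si for si in s))
    return EstimateResult(x_hat_seq=X, x_hat_now=X[-1].copy(),
                          eps_seq=eps, s_seq=s, objective=obj)


def advance_window(window: EstimationWindow, new_t: float, new_u: float,
                   new_y: np.ndarray, new_w: np.ndarray,
                   new_mats: LPVMatrices,
                   prev_result: EstimateResult | None = None) -> EstimationWindow:
    """FIFO-shift the window by one sample.

    The oldest record is dropped and the arrival prior moves to the
    previous window's smoothed estimate at the new window start.
    """
    if new_t <= window.t_hist[-1]:
        raise ValueError("time stamp regression in advance_window")
    x_prior = (prev_result.x_hat_seq[1].copy() if prev_result is not None
               else window.x_prior)
    return EstimationWindow(
        N=window.N,
        t_hist=window.t_hist[1:] + [new_t],
        u_hist=window.u_hist[1:] + [new_u],
        y_hist=window.y_hist[1:] + [np.asarray(new_y, dtype=float)],
        w_hist=window.w_hist[1:] + [np.asarray(new_w, dtype=float)],
        mat_hist=window.mat_hist[1:] + [new_mats],
        x_prior=x_prior, Po=window.Po, Q=window.Q, R=window.R,
    )


class MovingHorizonEstimator:
    """Stateful estimator driving :func:`estimate` in closed loop.

    Keeps the measurement/input/matrix histories, bootstraps the
    scheduling matrices from the previously estimated trajectory, solves
    a growing-window problem during startup (k < N) and a fixed-N window
    afterwards.
    """

    def __init__(self, params: PlantParameters, cfg: MHEConfig | None = None):
        self.params = params
        self.cfg = cfg or MHEConfig()
        self.t_hist: list = []
        self.u_hist: list = []
        self.y_hist: list = []
        self.w_hist: list = []
        self.inf_hist: list = []   # influent record per dynamics interval
        self.x_prior = np.asarray(self.cfg.x0_guess, dtype=float)
        self.last_result: EstimateResult | None = None

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(NX), np.asarray(self.cfg.x_max, dtype=float)

    def _bootstrap_state(self, y: np.ndarray) -> np.ndarray:
        """Initial estimate: measured outputs + configured guesses."""
        x = np.asarray(self.cfg.x0_guess, dtype=float).copy()
        x[[IX_SO, IX_SNH, IX_SNO]] = np.maximum(y, 0.0)
        return x

    def update(self, t: float, y: np.ndarray,
               u_prev: float | None = None,
               influent_prev: InfluentRecord | None = None) -> np.ndarray:
        """Ingest the sample at time t and return the current estimate.

        ``u_prev`` and ``influent_prev`` are the input and influent that
        acted over the preceding sampling interval; they are not needed on
        the first call.
        """
        y = np.asarray(y, dtype=float)
        if self.t_hist and t <= self.t_hist[-1]:
            raise ValueError("time stamp regression in MHE update")
        if not self.t_hist:
            self.t_hist.append(t)
            self.y_hist.append(y)
            x0 = self._bootstrap_state(y)
            self.x_prior = x0.copy()
            self.last_result = EstimateResult(
                x_hat_seq=x0[None, :], x_hat_now=x0,
                eps_seq=np.zeros((0, NX)), s_seq=np.zeros((0, NY)),
                objective=0.0)
            return x0

        if u_prev is None or influent_prev is None:
            raise ValueError("u_prev and influent_prev required after startup")
        self.t_hist.append(t)
        self.u_hist.append(float(u_prev))
        self.y_hist.append(y)
        self.w_hist.append(influent_prev.exogenous())
        self.inf_hist.append(influent_prev)

        if len(self.u_hist) > self.cfg.N:          # fixed-N sliding window
            self.t_hist.pop(0)
            self.u_hist.pop(0)
            self.y_hist.pop(0)
            self.w_hist.pop(0)
            self.inf_hist.pop(0)
            if self.last_result.x_hat_seq.shape[0] >= 2:
                self.x_prior = self.last_result.x_hat_seq[1].copy()

        # scheduling trajectory: previous window's estimate, shifted and
        # extended by propagating the last node one step
        N = len(self.u_hist)
        x_traj = list(self.last_result.x_hat_seq[-N:]) \
            if self.last_result.x_hat_seq.shape[0] >= N \
            else list(self.last_result.x_hat_seq)
        while len(x_traj) < N:
            x_traj.append(x_traj[-1])

        result = None
        x_traj = [np.asarray(v, dtype=float) for v in x_traj]
        for it in range(max(self.cfg.n_iter, 1)):
            mat_hist = [
                discretize_along(np.maximum(x_traj[i], 0.0),
                                 self.inf_hist[i], self.u_hist[i],
                                 self.t_hist[i + 1] - self.t_hist[i],
                                 self.cfg.n_substeps, self.params)
                for i in range(N)]
            window = EstimationWindow(
                N=N, t_hist=list(self.t_hist),
                u_hist=list(self.u_hist), y_hist=list(self.y_hist),
                w_hist=list(self.w_hist), mat_hist=mat_hist,
                x_prior=self.x_prior.copy(),
                Po=self.cfg.Po, Q=self.cfg.Q, R=self.cfg.R)
            result = estimate(window, self.bounds)
            # damped re-linearization: successive substitution on the
            # scheduling trajectory overshoots near Monod half-saturation,
            # so relax halfway toward the new estimate
            x_traj = [0.5 * (old + new) for old, new in
                      zip(x_traj, result.x_hat_seq[:-1])]
        self.last_result = result
        return result.x_hat_now
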