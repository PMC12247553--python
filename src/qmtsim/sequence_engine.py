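"""Hybrid-state pulse-train representation and spin propagation.

A cycle consists of a rectangular pi inversion pulse flanked by crusher
gradients, followed by ``n_pulses`` repetition intervals.  Each interval
holds one rectangular RF pulse of flip angle ``alpha_n`` and duration
``T_RF,n`` followed by free precession; gradient moments are balanced, and
the RF phase alternates by pi between consecutive pulses.  The signal is
sampled at the echo, TR/2 after the pulse center, and demodulated for the
phase alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .exceptions import DegenerateDynamicsError
from .mt_core import (LinearizedR2sGrid, SystemPars, TissuePars,
                      build_generator, default_r2sl_grid)

__all__ = [
    "PulseTrain",
    "Fingerprint",
    "default_train",
    "interval_propagator",
    "inversion_operator",
    "cycle_propagator",
    "periodic_state",
    "simulate_fingerprint",
]

DEFAULT_TR = 3.5e-3
DEFAULT_CYCLE_TIME = 4.0
DEFAULT_N_PULSES = 1142
DEFAULT_INV_TRF = 500e-6  # inversion-pulse duration (configurable, D7)

# crusher contract of the inversion: transverse components are spoiled
_CRUSH = np.diag([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])


@dataclass(frozen=True)
class PulseTrain:
    """Per-pulse flip angles and durations plus global timing.

    ``alpha`` in rad (0..pi), ``trf`` in s (0 < trf < tr); ``inv_trf`` is
    the inversion-pulse duration; ``cycle_time`` the full repetition period
    of the train.
    """

    alpha: np.ndarray
    trf: np.ndarray
    tr: float = DEFAULT_TR
    inv_trf: float = DEFAULT_INV_TRF
    cycle_time: float = DEFAULT_CYCLE_TIME
    invert: bool = True

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, float))
        object.__setattr__(self, "trf", np.asarray(self.trf, float))
        a, t = self.alpha, self.trf
        if a.ndim != 1 or a.shape != t.shape:
            raise ValueError("alpha and trf must be 1-D arrays of equal length")
        bad = np.nonzero((a < 0) | (a > np.pi))[0]
        if bad.size:
            raise ValueError(f"flip angles outside [0, pi] at indices {bad.tolist()}")
        bad = np.nonzero((t <= 0) | (t >= self.tr))[0]
        if bad.size:
            raise ValueError(
                f"pulse durations outside (0, TR) at indices {bad.tolist()}")
        if not self.inv_trf > 0:
            raise ValueError("inversion duration must be > 0")
        if a.size * self.tr > self.cycle_time + self.tr:
            raise ValueError("n_pulses * TR exceeds cycle_time + TR")

    @property
    def n_pulses(self) -> int:
        return self.alpha.size

    def replace(self, **kw) -> "PulseTrain":
        d = dict(alpha=self.alpha, trf=self.trf, tr=self.tr,
                 inv_trf=self.inv_trf, cycle_time=self.cycle_time,
                 invert=self.invert)
        d.update(kw)
        return PulseTrain(**d)


@dataclass(frozen=True)
class Fingerprint:
    """Complex per-TR signal with its sampling/demodulation convention."""

    signal: np.ndarray
    sampling: str = "echo"        # "echo" (TR/2 after pulse center) | "post_pulse"
    demodulated: bool = True

    def __post_init__(self):
        object.__setattr__(self, "signal",
                           np.asarray(self.signal, complex))
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("fingerprint entries must be finite")

    def __len__(self):
        return self.signal.size


def _smooth_resample(ctrl: np.ndarray, n: int) -> np.ndarray:
    """Evaluate a natural cubic spline through control values at n points."""
    from scipy.interpolate import CubicSpline
    x = np.linspace(0.0, 1.0, ctrl.size)
    return CubicSpline(x, ctrl, bc_type="natural")(np.linspace(0.0, 1.0, n))


# Control points of the shipped default pattern (D8): smooth flip-angle and
# pulse-duration modulation covering inversion-recovery and saturation
# contrast regimes.  The published optimized patterns are not available.
_DEF_ALPHA_CTRL = np.array([0.10, 0.60, 1.20, 0.35, 1.50, 0.70, 0.15,
                            1.00, 1.80, 0.40, 0.90, 0.20])
_DEF_TRF_CTRL = np.array([300., 500., 900., 250., 650., 1000., 350.,
                          150., 450., 800., 250., 500.]) * 1e-6


def default_train(n_pulses: int = DEFAULT_N_PULSES, tr: float = DEFAULT_TR,
                  cycle_time: float = DEFAULT_CYCLE_TIME,
                  inv_trf: float = DEFAULT_INV_TRF) -> PulseTrain:
    """Shipped default train: smooth spline-parameterized alpha/T_RF pattern."""
    alpha = np.clip(_smooth_resample(_DEF_ALPHA_CTRL, n_pulses), 0.0, np.pi)
    trf = np.clip(_smooth_resample(_DEF_TRF_CTRL, n_pulses), 100e-6,
                  min(1e-3, 0.9 * tr))
    return PulseTrain(alpha=alpha, trf=trf, tr=tr, inv_trf=inv_trf,
                      cycle_time=cycle_time)


# ---------------------------------------------------------------------------
# Propagators
# ---------------------------------------------------------------------------

def interval_propagator(generator: np.ndarray, dt: float) -> np.ndarray:
    """exp(dt * generator); exact for piecewise-constant coefficients."""
    generator = np.asarray(generator, float)
    if not np.all(np.isfinite(generator)):
        raise ValueError("generator entries must be finite")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return np.eye(generator.shape[0])
    return expm(generator * dt)


def _expm_many(A: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Batched matrix exponentials exp(A_i * dt_i) via eigendecomposition.

    Falls back to scaling-and-squaring for matrices whose eigenbasis is
    ill-conditioned (near-defective generators).
    """
    lam, V = np.linalg.eig(A)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return np.array([expm(a * t) for a, t in zip(A, dt)])
    recon = ((V * lam[:, None, :]) @ Vinv).real
    scale = 1.0 + np.abs(A).max(axis=(1, 2))
    bad = np.abs(recon - A).max(axis=(1, 2)) > 1e-11 * scale
    E = np.exp(lam * np.asarray(dt)[:, None])
    P = ((V * E[:, None, :]) @ Vinv).real
    for i in np.nonzero(bad)[0]:
        P[i] = expm(A[i] * dt[i])
    return P


def _expm_same_generator(G: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """exp(G * dt_i) for one generator and many durations (single eig)."""
    lam, V = np.linalg.eig(G)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return np.array([expm(G * t) for t in dts])
    recon = ((V * lam[None, :]) @ Vinv).real
    if np.abs(recon - G).max() > 1e-11 * (1.0 + np.abs(G).max()):
        return np.array([expm(G * t) for t in dts])
    E = np.exp(lam[None, :] * np.asarray(dts)[:, None])
    return ((V[None, :, :] * E[:, None, :]) @ Vinv).real


def inversion_operator(tissue: TissuePars, inv_trf: float = DEFAULT_INV_TRF,
                       b1: float = 1.0, wz: float = 0.0,
                       grid: LinearizedR2sGrid | None = None) -> np.ndarray:
    """Rectangular pi inversion pulse followed by crusher gradients.

    The nominal pi flip is scaled by b1 (``wy = b1 * pi / T_RF_inv``); the
    T2-selective character arises from the semi-solid saturation encoded in
    R2s,l.  The crushers zero xf, yf and xs exactly.
    """
    if not inv_trf > 0:
        raise ValueError("inversion duration must be > 0")
    grid = grid or default_r2sl_grid()
    alpha_eff = b1 * np.pi
    r2sl = grid.evaluate(alpha_eff, inv_trf, tissue.T2s)
    G = build_generator(tissue, b1 * np.pi / inv_trf, wz, r2sl)
    return _CRUSH @ expm(G * inv_trf)


class _CycleOps:
    """Per-segment generators and propagators of one cycle.

    Segment order: inversion (+crush), then for each pulse n a pulse
    propagator and two identical half-free-interval propagators (the echo
    lies between them), then a terminal free gap that pads the cycle to
    ``cycle_time``.
    """

    def __init__(self, train: PulseTrain, tissue: TissuePars, sys: SystemPars,
                 grid: LinearizedR2sGrid | None = None):
        grid = grid or default_r2sl_grid()
        self.train, self.tissue, self.sys, self.grid = train, tissue, sys, grid
        n = train.n_pulses
        sign = (-1.0) ** np.arange(n)
        self.sign = sign
        alpha_eff = sys.b1 * train.alpha
        self.alpha_eff = alpha_eff
        self.wy = sign * alpha_eff / train.trf
        self.r2sl = np.atleast_1d(grid.evaluate(alpha_eff, train.trf, tissue.T2s))

        base = build_generator(tissue, 0.0, sys.omega_z, 0.0)
        self.G_pulse = np.broadcast_to(base, (n, 6, 6)).copy()
        self.G_pulse[:, 0, 2] = self.wy
        self.G_pulse[:, 2, 0] = -self.wy
        self.G_pulse[:, 3, 4] = self.wy
        self.G_pulse[:, 4, 3] = -self.wy
        self.G_pulse[:, 3, 3] = -self.r2sl
        # free precession: semi-solid transverse decay at its intrinsic rate
        self.G_free = build_generator(tissue, 0.0, sys.omega_z, 1.0 / tissue.T2s)
        self.dt_half = 0.5 * (train.tr - train.trf)
        inv_time = train.inv_trf if train.invert else 0.0
        self.gap = max(train.cycle_time - n * train.tr - inv_time, 0.0)

        self.P_pulse = _expm_many(self.G_pulse, train.trf)
        self.P_half = _expm_same_generator(self.G_free, self.dt_half)
        self.P_gap = interval_propagator(self.G_free, self.gap)
        self.P_inv = (inversion_operator(tissue, train.inv_trf, sys.b1,
                                         sys.omega_z, grid)
                      if train.invert else np.eye(6))

    def cycle_matrix(self) -> np.ndarray:
        P = self.P_inv.copy()
        for i in range(self.train.n_pulses):
            P = self.P_half[i] @ (self.P_half[i] @ (self.P_pulse[i] @ P))
        return self.P_gap @ P

    def record(self, state: np.ndarray, sampling: str = "echo"):
        """Propagate one cycle from ``state`` (at cycle start, pre-inversion);
        return the per-TR recorded (xf, yf) pairs."""
        x = self.P_inv @ state
        out = np.empty((self.train.n_pulses, 2))
        for i in range(self.train.n_pulses):
            x = self.P_pulse[i] @ x
            if sampling == "post_pulse":
                out[i] = x[:2]
                x = self.P_half[i] @ (self.P_half[i] @ x)
            else:
                x = self.P_half[i] @ x
                out[i] = x[:2]
                x = self.P_half[i] @ x
        return out, self.P_gap @ x


def cycle_propagator(train: PulseTrain, tissue: TissuePars, sys: SystemPars,
                     grid: LinearizedR2sGrid | None = None) -> np.ndarray:
    """Affine propagator of the full cycle (inversion + pulse train + gap)."""
    return _CycleOps(train, tissue, sys, grid).cycle_matrix()


def periodic_state(cycle: np.ndarray) -> np.ndarray:
    """Unique fixed point of the cycle map (periodic boundary condition)."""
    cycle = np.asarray(cycle, float)
    A5 = cycle[:5, :5]
    b = cycle[:5, 5]
    M = np.eye(5) - A5
    if np.linalg.cond(M) > 1e14:
        raise DegenerateDynamicsError(
            "cycle map has no unique periodic state (I - A singular)")
    m = np.linalg.solve(M, b)
    return np.concatenate([m, [1.0]])


def simulate_fingerprint(train: PulseTrain, tissue: TissuePars,
                         sys: SystemPars,
                         grid: LinearizedR2sGrid | None = None,
                         sampling: str = "echo") -> Fingerprint:
    """Periodic-steady-state fingerprint ``s_n = M0 (xf + i yf)``.

    The signal is read out at the echo (TR/2 after the pulse center, D6) and
    demodulated for the pi phase increment by the per-pulse sign (D5).
    """
    if sampling not in ("echo", "post_pulse"):
        raise ValueError(f"unknown sampling convention {sampling!r}")
    ops = _CycleOps(train, tissue, sys, grid)
    m = periodic_state(ops.cycle_matrix())
    xy, _ = ops.record(m, sampling=sampling)
    s = sys.M0 * (xy[:, 0] + 1j * xy[:, 1]) * ops.sign
    return Fingerprint(signal=s, sampling=sampling)


def _signal(train, tissue, sys, grid=None, sampling="echo") -> np.ndarray:
    """Bare complex signal array (internal fast path for CRB/fitting)."""
    return simulate_fingerprint(train, tissue, sys, grid, sampling).signal
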