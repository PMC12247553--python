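"""Two-pool magnetization-transfer core.

Domain types for tissue/system parameters and the 6-component spin state,
the super-Lorentzian lineshape Green's function, generalized-Bloch
saturation of the semi-solid pool during a rectangular RF pulse, the
linearized transverse relaxation rate that reproduces the end-of-pulse
longitudinal magnetization, and assembly of the 6x6 spin-dynamics
generator.

Unit conventions: angles in rad, durations in s, rates in 1/s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import h5py
import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import brentq
from scipy.special import erf

from .exceptions import ConfigurationError, NumericalError

__all__ = [
    "TissuePars",
    "SystemPars",
    "equilibrium_state",
    "validate_state",
    "superlorentzian_green",
    "green_running_integral",
    "saturate_semisolid_pulse",
    "linearize_R2s",
    "LinearizedR2sGrid",
    "default_r2sl_grid",
    "build_generator",
]

# Gauss-Legendre rule on [0, 1] for the lineshape zeta integral.  501 nodes
# resolve the stationary-phase region around zeta = 1/sqrt(3) down to
# tau ~ 100 T2s (integrand width ~ T2s/tau).
_gl_x, _gl_w = np.polynomial.legendre.leggauss(501)
_ZETA = 0.5 * (_gl_x + 1.0)
_ZW = 0.5 * _gl_w
_ZC = (3.0 * _ZETA**2 - 1.0) ** 2 / 8.0  # lineshape exponent coefficients


@dataclass(frozen=True)
class TissuePars:
    """Biophysical unknowns of the unconstrained two-pool MT model.

    Pool sizes are normalized so that ``m0f + m0s = 1``; ``m0f`` is derived.

    Parameters
    ----------
    m0s : float
        Fractional semi-solid pool size, ``0 <= m0s < 1``.
    R1f, R2f : float
        Longitudinal/transverse relaxation rates of the free pool (1/s).
    Rx : float
        Exchange rate between the pools (1/s).
    R1s : float
        Longitudinal relaxation rate of the semi-solid pool (1/s).
    T2s : float
        Characteristic transverse relaxation time of the semi-solid pool (s).
    """

    m0s: float
    R1f: float
    R2f: float
    Rx: float
    R1s: float
    T2s: float

    def __post_init__(self):
        if not 0.0 <= self.m0s < 1.0:
            raise ValueError(f"m0s must be in [0, 1), got {self.m0s}")
        for name in ("R1f", "R2f", "Rx", "R1s"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.T2s > 0.0:
            raise ValueError(f"T2s must be > 0, got {self.T2s}")

    @property
    def m0f(self) -> float:
        return 1.0 - self.m0s

    def replace(self, **kw) -> "TissuePars":
        d = dict(m0s=self.m0s, R1f=self.R1f, R2f=self.R2f, Rx=self.Rx,
                 R1s=self.R1s, T2s=self.T2s)
        d.update(kw)
        return TissuePars(**d)


@dataclass(frozen=True)
class SystemPars:
    """Per-voxel system parameters.

    omega_z is the off-resonance frequency (rad/s), b1 the dimensionless
    transmit-field scale (actual Rabi frequency = b1 * nominal), and M0 the
    complex signal scale (spin density x coil sensitivity).
    """

    omega_z: float = 0.0
    b1: float = 1.0
    M0: complex = 1.0 + 0.0j

    def __post_init__(self):
        if not self.b1 > 0.0:
            raise ValueError(f"b1 must be > 0, got {self.b1}")
        if not abs(self.M0) > 0.0:
            raise ValueError("M0 must be non-zero")

    def replace(self, **kw) -> "SystemPars":
        d = dict(omega_z=self.omega_z, b1=self.b1, M0=self.M0)
        d.update(kw)
        return SystemPars(**d)


def equilibrium_state(tissue: TissuePars) -> np.ndarray:
    """Thermal-equilibrium spin state ``(xf, yf, zf, xs, zs, 1)``."""
    return np.array([0.0, 0.0, tissue.m0f, 0.0, tissue.m0s, 1.0])


def validate_state(state: np.ndarray, tissue: TissuePars, tol: float = 1e-9) -> None:
    """Check SpinState invariants; raise ValueError on violation."""
    state = np.asarray(state, float)
    if state.shape != (6,):
        raise ValueError(f"state must be a 6-vector, got shape {state.shape}")
    if abs(state[5] - 1.0) > tol:
        raise ValueError("homogeneous coordinate must equal 1")
    if np.sqrt(state[0] ** 2 + state[1] ** 2 + state[2] ** 2) > tissue.m0f + tol:
        raise ValueError("free-pool magnetization exceeds m0f")
    if abs(state[4]) > tissue.m0s + tol:
        raise ValueError("|zs| exceeds m0s")


# ---------------------------------------------------------------------------
# Super-Lorentzian lineshape
# ---------------------------------------------------------------------------

def superlorentzian_green(tau, t2s: float):
    """Free-decay attenuation G(tau) of the super-Lorentzian lineshape.

    ``G(tau) = int_0^1 exp(-(tau/T2s)^2 (3 zeta^2 - 1)^2 / 8) dzeta``,
    evaluated with a fixed high-order Gauss-Legendre rule.  Accepts scalar
    or array ``tau``; returns a value in (0, 1], non-increasing in tau.
    """
    if not t2s > 0.0:
        raise ValueError(f"T2s must be > 0, got {t2s}")
    tau_arr = np.asarray(tau, float)
    if np.any(tau_arr < 0.0):
        raise ValueError("tau must be non-negative")
    u2 = (tau_arr[..., None] / t2s) ** 2
    g = np.exp(-u2 * _ZC) @ _ZW
    return float(g) if np.isscalar(tau) or tau_arr.ndim == 0 else g


def green_running_integral(u, t2s: float):
    """Running integral ``H(u) = int_0^u G(v) dv`` of the Green's function.

    The inner time integral is available in closed form through erf, leaving
    a single smooth zeta quadrature.  Vectorized over ``u``.
    """
    if not t2s > 0.0:
        raise ValueError(f"T2s must be > 0, got {t2s}")
    u_arr = np.atleast_1d(np.asarray(u, float))
    a = _ZC / t2s**2
    sa = np.sqrt(a)
    # a -> 0 at zeta = 1/sqrt(3): integral degenerates to u itself
    safe = sa > 1e-12 / t2s
    inner = np.empty((u_arr.size, sa.size))
    inner[:, safe] = (0.5 * np.sqrt(np.pi) / sa[safe]) * erf(
        sa[safe] * u_arr[:, None]
    )
    inner[:, ~safe] = u_arr[:, None]
    out = inner @ _ZW
    return float(out[0]) if np.isscalar(u) or np.asarray(u).ndim == 0 else out


# ---------------------------------------------------------------------------
# Generalized-Bloch saturation during a rectangular pulse
# ---------------------------------------------------------------------------

_MIN_STEPS = 16


def _saturate_dimensionless(alphas: np.ndarray, ratio: float, n_steps: int) -> np.ndarray:
    """zs at pulse end for flip angles ``alphas`` and ratio = T_RF/T2s.

    Works in units of T2s.  Solves the second-kind Volterra equation
    ``zs(t) = 1 - wy^2 int_0^t H(t - tau) zs(tau) dtau`` (obtained by
    integrating the integro-differential form once) with the composite
    trapezoidal product-integration rule; vectorized over flip angles.
    """
    h = ratio / n_steps
    t = np.arange(n_steps + 1) * h
    Hv = green_running_integral(t, 1.0)
    wy2h = (np.asarray(alphas, float) / ratio) ** 2 * h
    zs = np.empty((n_steps + 1, wy2h.size))
    zs[0] = 1.0
    for n in range(1, n_steps + 1):
        s = 0.5 * Hv[n] * zs[0]
        if n > 1:
            s = s + Hv[n - 1:0:-1] @ zs[1:n]
        zs[n] = 1.0 - wy2h * s
    return zs[n_steps]


def saturate_semisolid_pulse(alpha: float, trf: float, t2s: float,
                             n_steps: int = 600) -> float:
    """Semi-solid longitudinal attenuation ``zs(T_RF)/zs(0)``.

    Solves the generalized-Bloch integro-differential equation
    ``dzs/dt = -wy^2 int_0^t G(t - tau) zs(tau) dtau`` for a rectangular
    pulse of constant ``wy = alpha/T_RF``, with longitudinal relaxation and
    exchange frozen during the pulse.  Product integration of the
    equivalent second-kind Volterra equation, O(h^2) accurate.
    """
    if not trf > 0.0:
        raise ValueError(f"T_RF must be > 0, got {trf}")
    if not t2s > 0.0:
        raise ValueError(f"T2s must be > 0, got {t2s}")
    if n_steps < _MIN_STEPS:
        raise ConfigurationError(
            f"n_steps={n_steps} below minimum of {_MIN_STEPS}")
    if alpha == 0.0:
        return 1.0
    return float(_saturate_dimensionless(np.array([alpha]), trf / t2s, n_steps)[0])


def _linear_zs_end(x, alpha):
    """zs(T_RF) of the linearized 2x2 model, as a function of x = R * T_RF.

    Propagates (xs, zs) = (0, 1) with generator [[-R, wy], [-wy, 0]] over
    T_RF (wy * T_RF = alpha); closed-form 2x2 matrix exponential, split into
    over/underdamped branches for numerical stability at large x.
    """
    x = np.atleast_1d(np.asarray(x, float))
    m = -x / 2.0
    q2 = m**2 - alpha**2
    q = np.sqrt(np.abs(q2))
    out = np.empty_like(x)
    pos = q2 > 0
    if pos.any():
        # overdamped: both m+q and m-q are <= 0, exponentials stay bounded
        ep = np.exp(m[pos] + q[pos])
        en = np.exp(m[pos] - q[pos])
        out[pos] = 0.5 * (ep + en) - 0.5 * (m[pos] / q[pos]) * (ep - en)
    neg = ~pos
    if neg.any():
        y = q[neg]
        sinc = np.where(y < 1e-8, 1.0 - y**2 / 6.0,
                        np.sin(y) / np.where(y < 1e-8, 1.0, y))
        out[neg] = np.exp(m[neg]) * (np.cos(y) - m[neg] * sinc)
    return out


def linearize_R2s(alpha: float, trf: float, t2s: float,
                  n_steps: int = 600, zs_target: float | None = None) -> float:
    """Linearized transverse relaxation rate R2s,l (1/s).

    Root R of: propagating (xs, zs) through the rectangular pulse with an
    exponential transverse decay R instead of the non-exponential
    generalized-Bloch kernel yields the same zs at pulse end.  By
    convention R2s,l(alpha=0) = 0 (no irradiation, rate unobservable).
    """
    if alpha == 0.0:
        return 0.0
    if alpha < 0.0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if zs_target is None:
        zs_target = saturate_semisolid_pulse(alpha, trf, t2s, n_steps=n_steps)
    x = _linearize_dimensionless(alpha, zs_target, best_effort=False)
    return x / trf


def _linearize_dimensionless(alpha: float, zs_target: float,
                             best_effort: bool = True) -> float:
    """Solve ``_linear_zs_end(x, alpha) == zs_target`` for x = R * T_RF.

    Scans a dense log ladder for the first sign change and polishes with
    Brent's method.  For alpha > pi the generalized-Bloch value can lie
    outside the linear model's reachable set; with ``best_effort`` the
    closest-achieving x is returned, otherwise a NumericalError is raised.
    """

    def f(x):
        return float(_linear_zs_end(np.array([x]), alpha)[0]) - zs_target

    xs = np.concatenate([[0.0], np.geomspace(1e-6, 1e8, 1200)])
    fs = _linear_zs_end(xs, alpha) - zs_target
    if fs[0] == 0.0:
        return 0.0
    sign_change = np.nonzero(fs[:-1] * fs[1:] <= 0.0)[0]
    if sign_change.size == 0:
        if best_effort:
            i = int(np.argmin(np.abs(fs)))
            from scipy.optimize import minimize_scalar
            lo = xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]
            res = minimize_scalar(lambda x: abs(f(x)), bounds=lo,
                                  method="bounded",
                                  options={"xatol": 1e-12})
            return float(res.x)
        raise NumericalError(
            f"R2s,l root not bracketed for alpha={alpha}: "
            f"zs_target={zs_target}")
    i = int(sign_change[0])
    return brentq(f, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16, maxiter=200)


# ---------------------------------------------------------------------------
# Precomputed R2s,l lookup grid
# ---------------------------------------------------------------------------

class LinearizedR2sGrid:
    """Bicubic lookup table of ``R2s,l * T2s`` over (alpha, log(T_RF/T2s)).

    The linearized rate is a two-parameter dimensionless function: scaling
    time by T2s leaves only the flip angle and the ratio T_RF/T2s.  The
    grid covers alpha in (0, alpha_max] and ratio on a log axis; queries
    below the smallest tabulated alpha are clamped (the semi-solid pool is
    essentially untouched there), ratio queries are clamped to the table
    range.  Direct evaluation via :func:`linearize_R2s` is the slow path.
    """

    def __init__(self, alphas: np.ndarray, log_ratios: np.ndarray,
                 values: np.ndarray, meta: dict | None = None):
        alphas = np.asarray(alphas, float)
        log_ratios = np.asarray(log_ratios, float)
        values = np.asarray(values, float)
        if values.shape != (alphas.size, log_ratios.size):
            raise ValueError("values shape does not match axes")
        if not (np.all(np.diff(alphas) > 0) and np.all(np.diff(log_ratios) > 0)):
            raise ValueError("grid axes must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("grid values must be finite and >= 0")
        self.alphas = alphas
        self.log_ratios = log_ratios
        self.values = values
        self.meta = dict(meta or {})
        self._spline = RectBivariateSpline(alphas, log_ratios, values, kx=3, ky=3)

    @classmethod
    def build(cls, n_alpha: int = 48, n_ratio: int = 48,
              alpha_max: float = 1.6 * np.pi,
              ratio_min: float = 1.0, ratio_max: float = 1100.0,
              n_steps: int = 600) -> "LinearizedR2sGrid":
        alphas = np.linspace(0.02, alpha_max, n_alpha)
        log_ratios = np.linspace(np.log(ratio_min), np.log(ratio_max), n_ratio)
        values = np.empty((n_alpha, n_ratio))
        for j, lr in enumerate(log_ratios):
            ratio = np.exp(lr)
            zs_end = _saturate_dimensionless(alphas, ratio, n_steps)
            for i, a in enumerate(alphas):
                # dimensionless solve: x = R * T_RF, stored value = R * T2s.
                # Exact root for alpha <= pi; best approximation beyond
                # (reachable only with b1 > 1), where the non-exponential
                # decay can undershoot the linear model's range.
                x = _linearize_dimensionless(a, float(zs_end[i]),
                                             best_effort=a > np.pi)
                values[i, j] = x / ratio
        meta = dict(n_steps=n_steps, alpha_max=alpha_max,
                    ratio_min=ratio_min, ratio_max=ratio_max)
        return cls(alphas, log_ratios, values, meta)

    def evaluate(self, alpha, trf, t2s):
        """Interpolated R2s,l (1/s); vectorized over alpha/trf."""
        alpha = np.asarray(alpha, float)
        trf = np.asarray(trf, float)
        scalar = alpha.ndim == 0 and trf.ndim == 0
        alpha, trf = np.broadcast_arrays(np.atleast_1d(alpha), np.atleast_1d(trf))
        a = np.clip(alpha, self.alphas[0], self.alphas[-1])
        lr = np.clip(np.log(trf / t2s), self.log_ratios[0], self.log_ratios[-1])
        out = self._spline(a, lr, grid=False) / t2s
        out = np.where(alpha == 0.0, 0.0, out)
        return float(out[0]) if scalar else out

    def evaluate_with_grads(self, alpha, trf, t2s):
        """Value plus partial derivatives wrt alpha and T2s.

        Returns ``(r2sl, d/dalpha, d/dT2s)``; used by the augmented-
        propagation derivative path.
        """
        alpha = np.atleast_1d(np.asarray(alpha, float))
        trf = np.atleast_1d(np.asarray(trf, float))
        alpha, trf = np.broadcast_arrays(alpha, trf)
        a = np.clip(alpha, self.alphas[0], self.alphas[-1])
        lr = np.clip(np.log(trf / t2s), self.log_ratios[0], self.log_ratios[-1])
        F = self._spline(a, lr, grid=False)
        dF_da = self._spline(a, lr, dx=1, grid=False)
        dF_dlr = self._spline(a, lr, dy=1, grid=False)
        val = F / t2s
        d_alpha = dF_da / t2s
        # R2s,l = F(alpha, log(trf/t2s)) / t2s ; d(log ratio)/dT2s = -1/T2s
        d_t2s = (-F - dF_dlr) / t2s**2
        zero = alpha == 0.0
        return (np.where(zero, 0.0, val), np.where(zero, 0.0, d_alpha),
                np.where(zero, 0.0, d_t2s))

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("alphas", data=self.alphas)
            f.create_dataset("log_ratios", data=self.log_ratios)
            f.create_dataset("values", data=self.values)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "LinearizedR2sGrid":
        with h5py.File(path, "r") as f:
            return cls(f["alphas"][:], f["log_ratios"][:], f["values"][:],
                       dict(f.attrs))


@lru_cache(maxsize=1)
def default_r2sl_grid() -> LinearizedR2sGrid:
    """Process-wide cached default lookup grid (built on first use)."""
    return LinearizedR2sGrid.build()


# ---------------------------------------------------------------------------
# Generator assembly
# ---------------------------------------------------------------------------

def build_generator(tissue: TissuePars, wy: float, wz: float,
                    r2sl: float) -> np.ndarray:
    """6x6 generator of the two-pool Bloch-McConnell dynamics.

    Acts on the homogeneous state ``(xf, yf, zf, xs, zs, 1)``; the last row
    is identically zero.  ``wy`` is the (signed) Rabi frequency, ``wz`` the
    off-resonance frequency, and ``r2sl`` the linearized semi-solid
    transverse relaxation rate active during the interval.
    """
    vals = (tissue.m0s, tissue.R1f, tissue.R2f, tissue.Rx, tissue.R1s,
            wy, wz, r2sl)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("generator inputs must be finite")
    m0s, m0f = tissue.m0s, tissue.m0f
    R1f, R2f, Rx, R1s = tissue.R1f, tissue.R2f, tissue.Rx, tissue.R1s
    A = np.zeros((6, 6))
    A[0, 0] = -R2f; A[0, 1] = -wz;  A[0, 2] = wy
    A[1, 0] = wz;   A[1, 1] = -R2f
    A[2, 0] = -wy;  A[2, 2] = -R1f - Rx * m0s; A[2, 4] = Rx * m0f
    A[2, 5] = m0f * R1f
    A[3, 3] = -r2sl; A[3, 4] = wy
    A[4, 2] = Rx * m0s; A[4, 3] = -wy; A[4, 4] = -R1s - Rx * m0f
    A[4, 5] = m0s * R1s
    return A
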