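"""Cramer-Rao-bound machinery for the hybrid-state fingerprint.

Signal derivatives with respect to the full unknown set (6 biophysical
parameters plus off-resonance, transmit scale and complex signal scale),
Fisher information under complex white Gaussian noise, per-unknown variance
bounds, a seconds-valued normalized CRB, and CRB-driven optimization of the
flip-angle/pulse-duration pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm_frechet

from .exceptions import NumericalError, SingularFisherError
from .mt_core import SystemPars, TissuePars, default_r2sl_grid
from .sequence_engine import (PulseTrain, _CycleOps, default_train,
                              periodic_state, _signal)

__all__ = [
    "LABELS",
    "UnknownSet",
    "CRBResult",
    "fingerprint_jacobian",
    "fisher",
    "crb_values",
    "normalized_crb",
    "crb_report",
    "optimize_train",
    "REFERENCE_TISSUE",
    "REFERENCE_SYSTEM",
]

LABELS = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s",
          "omega_z", "b1", "M0_re", "M0_im")
BIOPHYSICAL = LABELS[:6]

# reference point used for all train optimizations
REFERENCE_TISSUE = TissuePars(m0s=0.25, R1f=0.5, R2f=15.4, Rx=20.0,
                              R1s=2.0, T2s=10e-6)
REFERENCE_SYSTEM = SystemPars(omega_z=0.0, b1=1.0, M0=1.0 + 0.0j)

# absolute floors for finite-difference steps when a reference value is 0
_FD_FLOOR = {"m0s": 0.1, "R1f": 1.0, "R2f": 10.0, "Rx": 10.0, "R1s": 1.0,
             "T2s": 1e-5, "omega_z": 10.0, "b1": 1.0}


@dataclass(frozen=True)
class UnknownSet:
    """Ordered unknown labels with their reference values."""

    labels: tuple
    tissue: TissuePars
    sys: SystemPars

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("unknown labels must be unique")
        for lab in labels:
            if lab not in LABELS:
                raise ValueError(f"unknown parameter label {lab!r}")

    @property
    def values(self) -> np.ndarray:
        return np.array([get_param(lab, self.tissue, self.sys)
                         for lab in self.labels])


def get_param(label: str, tissue: TissuePars, sys: SystemPars) -> float:
    if label in BIOPHYSICAL:
        return getattr(tissue, label)
    if label == "omega_z":
        return sys.omega_z
    if label == "b1":
        return sys.b1
    if label == "M0_re":
        return sys.M0.real
    if label == "M0_im":
        return sys.M0.imag
    raise ValueError(f"unknown parameter label {label!r}")


def set_param(label: str, value: float, tissue: TissuePars,
              sys: SystemPars) -> tuple[TissuePars, SystemPars]:
    if label in BIOPHYSICAL:
        return tissue.replace(**{label: value}), sys
    if label == "omega_z":
        return tissue, sys.replace(omega_z=value)
    if label == "b1":
        return tissue, sys.replace(b1=value)
    if label == "M0_re":
        return tissue, sys.replace(M0=complex(value, sys.M0.imag))
    if label == "M0_im":
        return tissue, sys.replace(M0=complex(sys.M0.real, value))
    raise ValueError(f"unknown parameter label {label!r}")


@dataclass(frozen=True)
class CRBResult:
    """Fisher matrix, variance bounds and normalized bounds per unknown."""

    labels: tuple
    fisher: np.ndarray
    crb: np.ndarray
    ncrb: np.ndarray
    sigma2: float


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def fingerprint_jacobian(train: PulseTrain, tissue: TissuePars,
                         sys: SystemPars, labels=LABELS,
                         method: str = "central-finite-difference",
                         rel_step: float = 1e-4, grid=None) -> np.ndarray:
    """Complex Jacobian ``ds_n/dtheta_k`` (n_pulses x n_unknowns).

    The M0 columns are analytic (the signal is linear in M0); the remaining
    columns use either central finite differences with relative step
    ``rel_step`` (D11) or joint propagation of state and state derivative
    with block generators [[G, dG], [0, G]].
    """
    labels = tuple(labels)
    grid = grid or default_r2sl_grid()
    s0 = _signal(train, tissue, sys, grid)
    c = s0 / sys.M0
    J = np.empty((train.n_pulses, len(labels)), complex)
    if method == "central-finite-difference":
        for k, lab in enumerate(labels):
            J[:, k] = _fd_column(lab, train, tissue, sys, grid, rel_step, c)
    elif method == "augmented-propagation":
        aug = _AugmentedDerivatives(train, tissue, sys, grid)
        for k, lab in enumerate(labels):
            if lab == "M0_re":
                J[:, k] = c
            elif lab == "M0_im":
                J[:, k] = 1j * c
            else:
                J[:, k] = aug.column(lab)
    else:
        raise ValueError(f"unknown jacobian method {method!r}")
    if not np.all(np.isfinite(J)):
        bad = [labels[k] for k in range(len(labels))
               if not np.all(np.isfinite(J[:, k]))]
        raise NumericalError(f"non-finite signal derivative for {bad}")
    return J


def _fd_column(lab, train, tissue, sys, grid, rel_step, c):
    if lab == "M0_re":
        return c
    if lab == "M0_im":
        return 1j * c
    theta = get_param(lab, tissue, sys)
    h = rel_step * max(abs(theta), _FD_FLOOR[lab])
    tp, sp = set_param(lab, theta + h, tissue, sys)
    tm, sm = set_param(lab, theta - h, tissue, sys)
    return (_signal(train, tp, sp, grid) - _signal(train, tm, sm, grid)) / (2 * h)


class _AugmentedDerivatives:
    """Exact signal derivatives via joint (state, dstate) propagation.

    For each segment with generator G over dt, ``expm_frechet(G dt, dG dt)``
    yields the propagator and its directional derivative; products are
    accumulated with the product rule through the cycle, the periodic fixed
    point is differentiated implicitly, and (x, dx) are propagated through
    the recording pass.
    """

    def __init__(self, train, tissue, sys, grid):
        self.ops = _CycleOps(train, tissue, sys, grid)
        self.train, self.tissue, self.sys, self.grid = train, tissue, sys, grid
        self.m = periodic_state(self.ops.cycle_matrix())
        # cached r2sl gradients for pulse segments and the inversion
        self.r2sl_g = grid.evaluate_with_grads(self.ops.alpha_eff, train.trf,
                                               tissue.T2s)
        self.r2sl_inv_g = grid.evaluate_with_grads(
            np.array([sys.b1 * np.pi]), np.array([train.inv_trf]), tissue.T2s)

    # -- dG builders -------------------------------------------------------
    def _dG_common(self, lab):
        """Parameter derivative of the generator entries shared by all
        segments (relaxation/exchange structure); excludes wy/r2sl terms."""
        t = self.tissue
        d = np.zeros((6, 6))
        if lab == "m0s":
            d[2, 2] = -t.Rx; d[2, 4] = -t.Rx; d[2, 5] = -t.R1f
            d[4, 2] = t.Rx; d[4, 4] = t.Rx; d[4, 5] = t.R1s
        elif lab == "R1f":
            d[2, 2] = -1.0; d[2, 5] = t.m0f
        elif lab == "R2f":
            d[0, 0] = -1.0; d[1, 1] = -1.0
        elif lab == "Rx":
            d[2, 2] = -t.m0s; d[2, 4] = t.m0f
            d[4, 2] = t.m0s; d[4, 4] = -t.m0f
        elif lab == "R1s":
            d[4, 4] = -1.0; d[4, 5] = t.m0s
        return d

    def _segment_dGs(self, lab):
        """(dG_inv, dG_pulse (n,6,6), dG_free) for the given label."""
        ops, train, sys = self.ops, self.train, self.sys
        n = train.n_pulses
        base = self._dG_common(lab)
        dG_pulse = np.broadcast_to(base, (n, 6, 6)).copy()
        dG_inv = base.copy()
        dG_free = base.copy()
        if lab == "T2s":
            _, _, dr_dt2s = self.r2sl_g
            dG_pulse[:, 3, 3] = -dr_dt2s
            dG_inv[3, 3] = -float(self.r2sl_inv_g[2][0])
            dG_free[3, 3] = 1.0 / self.tissue.T2s**2
        elif lab == "omega_z":
            for d in (dG_inv, dG_free):
                d[0, 1] = -1.0; d[1, 0] = 1.0
            dG_pulse[:, 0, 1] = -1.0; dG_pulse[:, 1, 0] = 1.0
        elif lab == "b1":
            # wy = sign * b1 * alpha / trf and r2sl via alpha_eff = b1*alpha
            dwy = self.ops.sign * train.alpha / train.trf
            _, dr_da, _ = self.r2sl_g
            dG_pulse[:, 0, 2] = dwy; dG_pulse[:, 2, 0] = -dwy
            dG_pulse[:, 3, 4] = dwy; dG_pulse[:, 4, 3] = -dwy
            dG_pulse[:, 3, 3] = -dr_da * train.alpha
            dwy_i = np.pi / train.inv_trf
            dG_inv[0, 2] = dwy_i; dG_inv[2, 0] = -dwy_i
            dG_inv[3, 4] = dwy_i; dG_inv[4, 3] = -dwy_i
            dG_inv[3, 3] = -float(self.r2sl_inv_g[1][0]) * np.pi
        return dG_inv, dG_pulse, dG_free

    def column(self, lab: str) -> np.ndarray:
        ops, train, sys = self.ops, self.train, self.sys
        n = train.n_pulses
        dG_inv, dG_pulse, dG_free = self._segment_dGs(lab)

        def frechet(G, dG, dt):
            if dt == 0:
                return np.eye(6), np.zeros((6, 6))
            return expm_frechet(G * dt, dG * dt)

        from .sequence_engine import _CRUSH
        if train.invert:
            P_inv_raw, dP_inv_raw = frechet(self._inv_generator(), dG_inv,
                                            train.inv_trf)
            P_inv, dP_inv = _CRUSH @ P_inv_raw, _CRUSH @ dP_inv_raw
        else:
            P_inv, dP_inv = np.eye(6), np.zeros((6, 6))

        dP_pulse = np.empty((n, 6, 6))
        P_pulse = np.empty((n, 6, 6))
        dP_half = np.empty((n, 6, 6))
        P_half = np.empty((n, 6, 6))
        for i in range(n):
            P_pulse[i], dP_pulse[i] = frechet(ops.G_pulse[i], dG_pulse[i],
                                              train.trf[i])
            P_half[i], dP_half[i] = frechet(ops.G_free, dG_free,
                                            ops.dt_half[i])
        P_gap, dP_gap = frechet(ops.G_free, dG_free, ops.gap)

        # accumulate cycle propagator and its derivative
        C, dC = P_inv, dP_inv
        for i in range(n):
            for P, dP in ((P_pulse[i], dP_pulse[i]),
                          (P_half[i], dP_half[i]),
                          (P_half[i], dP_half[i])):
                dC = dP @ C + P @ dC
                C = P @ C
        dC = dP_gap @ C + P_gap @ dC
        C = P_gap @ C

        # implicit derivative of the periodic fixed point
        m = self.m
        A5 = C[:5, :5]
        dm5 = np.linalg.solve(np.eye(5) - A5, (dC[:5, :5] @ m[:5]) + dC[:5, 5])
        dm = np.concatenate([dm5, [0.0]])

        # recording pass with (x, dx)
        x, dx = P_inv @ m, dP_inv @ m + P_inv @ dm
        out = np.empty((n, 2))
        for i in range(n):
            x, dx = P_pulse[i] @ x, dP_pulse[i] @ x + P_pulse[i] @ dx
            x, dx = P_half[i] @ x, dP_half[i] @ x + P_half[i] @ dx
            out[i] = dx[:2]
            x, dx = P_half[i] @ x, dP_half[i] @ x + P_half[i] @ dx
        return sys.M0 * (out[:, 0] + 1j * out[:, 1]) * ops.sign

    def _inv_generator(self):
        from .mt_core import build_generator
        sys, train, tissue = self.sys, self.train, self.tissue
        r2sl = float(self.r2sl_inv_g[0][0])
        return build_generator(tissue, sys.b1 * np.pi / train.inv_trf,
                               sys.omega_z, r2sl)


# ---------------------------------------------------------------------------
# Fisher information and bounds
# ---------------------------------------------------------------------------

def fisher(J: np.ndarray, sigma2: float) -> np.ndarray:
    """Fisher matrix ``Re(J^H J) / sigma2`` for complex white noise of
    per-channel variance sigma2 on each sample."""
    if not sigma2 > 0:
        raise ValueError("sigma2 must be > 0")
    J = np.asarray(J)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    F = (J.conj().T @ J).real / sigma2
    return 0.5 * (F + F.T)


def crb_values(F: np.ndarray, labels=None) -> np.ndarray:
    """Diagonal of the inverse Fisher matrix (variance bounds per unknown).

    The singularity check and inversion act on the correlation-scaled
    Fisher matrix: diagonal rescaling reflects parameter units, not
    estimability, so the condition threshold is applied scale-invariantly.
    """
    F = np.asarray(F, float)
    d = np.sqrt(np.diag(F))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise SingularFisherError("Fisher matrix has non-positive diagonal")
    C = F / np.outer(d, d)
    cond = np.linalg.cond(C)
    if cond > 1e12:
        Coff = C.copy()
        np.fill_diagonal(Coff, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(Coff)), Coff.shape)
        pair = (labels[i], labels[j]) if labels is not None else (int(i), int(j))
        raise SingularFisherError(
            f"Fisher matrix condition {cond:.2e} > 1e12; most collinear "
            f"pair: {pair}", worst_pair=pair)
    Cinv = np.linalg.inv(C)
    return np.diag(Cinv) / d**2


def normalized_crb(crb, theta, t_cycle: float):
    """Seconds-valued normalized CRB ``crb * T_cycle / theta^2`` (D12).

    Under unit-variance noise per unit time this resembles the inverse
    squared SNR per unit scan time; any fixed convention preserves
    rankings.  Vectorized over unknowns.
    """
    crb = np.asarray(crb, float)
    theta = np.asarray(theta, float)
    if np.any(theta == 0):
        raise ValueError("normalized CRB undefined for zero reference value")
    out = crb * t_cycle / theta**2
    return float(out) if out.ndim == 0 else out


def crb_report(train: PulseTrain, tissue: TissuePars, sys: SystemPars,
               labels=LABELS, sigma2: float = 1.0,
               method: str = "central-finite-difference",
               grid=None) -> CRBResult:
    """Full CRB computation for one train at one reference point."""
    labels = tuple(labels)
    J = fingerprint_jacobian(train, tissue, sys, labels, method=method,
                             grid=grid)
    F = fisher(J, sigma2)
    crb = crb_values(F, labels)
    theta = np.array([get_param(lab, tissue, sys) for lab in labels])
    ncrb = np.full(len(labels), np.nan)
    nz = theta != 0
    ncrb[nz] = normalized_crb(crb[nz], theta[nz], train.cycle_time)
    return CRBResult(labels=labels, fisher=F, crb=crb, ncrb=ncrb,
                     sigma2=sigma2)


# ---------------------------------------------------------------------------
# Train optimization
# ---------------------------------------------------------------------------

def _train_from_controls(ctrl: np.ndarray, n_cp: int, template: PulseTrain,
                         alpha_bounds, trf_bounds) -> PulseTrain:
    from .sequence_engine import _smooth_resample
    n = template.n_pulses
    alpha = np.clip(_smooth_resample(ctrl[:n_cp], n), *alpha_bounds)
    trf = np.clip(_smooth_resample(ctrl[n_cp:], n), *trf_bounds)
    return template.replace(alpha=alpha, trf=trf)


def optimize_train(init: PulseTrain | None = None, weights: dict | None = None,
                   alpha_bounds=(0.0, np.pi), trf_bounds=(100e-6, 1e-3),
                   n_control_points: int = 8, maxiter: int = 20,
                   seed: int = 0, n_restarts: int = 3,
                   labels=LABELS, tissue: TissuePars = REFERENCE_TISSUE,
                   sys: SystemPars = REFERENCE_SYSTEM,
                   grid=None) -> tuple[PulseTrain, dict]:
    """Minimize the weighted sum of normalized CRBs over smooth trains.

    Flip angles and pulse durations are parameterized by natural cubic
    splines over ``n_control_points`` control values each, optimized with
    bounded L-BFGS-B from the initial pattern plus seeded random restarts
    (D13).  Returns the best train and a convergence log; the returned
    objective never exceeds the initial one.
    """
    if alpha_bounds[0] >= alpha_bounds[1] or trf_bounds[0] >= trf_bounds[1]:
        raise ValueError("infeasible bounds")
    init = init or default_train()
    if trf_bounds[1] >= init.tr:
        raise ValueError("trf upper bound must stay below TR")
    weights = weights or {lab: 1.0 for lab in BIOPHYSICAL}
    grid = grid or default_r2sl_grid()
    labels = tuple(labels)
    theta = np.array([get_param(lab, tissue, sys) for lab in labels])
    w = np.array([weights.get(lab, 0.0) for lab in labels])
    nz = theta != 0

    def train_objective(train):
        try:
            J = fingerprint_jacobian(train, tissue, sys, labels, grid=grid)
            crb = crb_values(fisher(J, 1.0), labels)
        except (SingularFisherError, NumericalError):
            return 1e12
        ncrb = np.zeros_like(crb)
        ncrb[nz] = normalized_crb(crb[nz], theta[nz], train.cycle_time)
        return float(np.sum(w * ncrb))

    def objective(ctrl):
        return train_objective(_train_from_controls(
            ctrl, n_control_points, init, alpha_bounds, trf_bounds))

    # initial control points: resample the init pattern
    idx = np.linspace(0, init.n_pulses - 1, n_control_points).astype(int)
    ctrl0 = np.concatenate([
        np.clip(init.alpha[idx], *alpha_bounds),
        np.clip(init.trf[idx], *trf_bounds)])
    f0 = train_objective(init)
    log = {"initial_objective": f0, "restarts": []}
    if maxiter == 0:
        log["objective"] = f0
        return init, log

    from scipy.optimize import minimize
    bounds = ([alpha_bounds] * n_control_points + [trf_bounds] * n_control_points)
    # scale trf controls into O(1) range for the optimizer
    scale = np.concatenate([np.ones(n_control_points),
                            np.full(n_control_points, 1e-3)])
    rng = np.random.default_rng(seed)
    best_train, best_f = init, f0
    starts = [ctrl0]
    for _ in range(max(n_restarts - 1, 0)):
        pert = ctrl0 * (1 + 0.3 * rng.standard_normal(ctrl0.size))
        starts.append(np.clip(pert, [b[0] for b in bounds],
                              [b[1] for b in bounds]))
    for ctrl_start in starts:
        res = minimize(lambda u: objective(u * scale), ctrl_start / scale,
                       method="L-BFGS-B",
                       bounds=[(b[0] / s, b[1] / s)
                               for b, s in zip(bounds, scale)],
                       options={"maxiter": maxiter, "maxfun": 50 * maxiter})
        log["restarts"].append({"objective": float(res.fun),
                                "nit": int(res.nit)})
        if res.fun < best_f:
            best_f = float(res.fun)
            best_train = _train_from_controls(res.x * scale, n_control_points,
                                              init, alpha_bounds, trf_bounds)
    if best_f >= f0:
        import warnings
        warnings.warn("optimization did not improve on the initial train",
                      RuntimeWarning, stacklevel=2)
    log["objective"] = best_f
    return best_train, log
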