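"""Dictionaries, subspace compression, and voxel-wise model fitting.

A coarse dictionary of simulated fingerprints provides (a) the singular-
vector subspace used to compress fingerprints to a low-rank coefficient
space and (b) nearest-atom initializations for the nonlinear fit.  The
voxel fit is a bounded trust-region least-squares over the 6 biophysical
parameters plus off-resonance, transmit scale and complex signal scale
(D14/D15); the observation may be a full fingerprint or a coefficient
vector, optionally normalized by its first coefficient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateVoxelError
from .mt_core import SystemPars, TissuePars, default_r2sl_grid
from .sequence_engine import Fingerprint, PulseTrain, _signal
from .crb import LABELS, get_param, set_param

__all__ = [
    "Dictionary",
    "Subspace",
    "FitResult",
    "DEFAULT_BOUNDS",
    "build_dictionary",
    "subspace",
    "compress",
    "fit_voxel",
    "fit_map",
    "fit_monoexp",
]

# D15: default fit bounds enclosing healthy-tissue values with margin
DEFAULT_BOUNDS = {
    "m0s": (0.0, 0.5),
    "R1f": (0.1, 5.0),
    "R2f": (1.0, 50.0),
    "Rx": (1.0, 100.0),
    "R1s": (0.1, 20.0),
    "T2s": (1e-6, 30e-6),
    "omega_z": (-2 * np.pi * 200, 2 * np.pi * 200),
    "b1": (0.5, 1.5),
    "M0_re": (-10.0, 10.0),
    "M0_im": (-10.0, 10.0),
}

# typical magnitudes used as trust-region scaling
_X_SCALE = {"m0s": 0.1, "R1f": 1.0, "R2f": 10.0, "Rx": 10.0, "R1s": 1.0,
            "T2s": 1e-5, "omega_z": 100.0, "b1": 0.5, "M0_re": 1.0,
            "M0_im": 1.0}

_DEFAULT_INIT = {"m0s": 0.15, "R1f": 0.6, "R2f": 14.0, "Rx": 15.0,
                 "R1s": 3.0, "T2s": 1.2e-5, "omega_z": 0.0, "b1": 1.0,
                 "M0_re": 1.0, "M0_im": 0.0}


@dataclass(frozen=True)
class Dictionary:
    """Coarse fingerprint dictionary over a rectangular parameter grid."""

    axes: dict
    atoms: np.ndarray          # (n_pulses, n_atoms) complex
    pars: tuple                # one (tissue, sys) per atom, axis-product order
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


@dataclass(frozen=True)
class Subspace:
    """Orthonormal rank-r basis of the dictionary's left singular vectors."""

    basis: np.ndarray          # (n_pulses, rank) complex
    svals: np.ndarray
    rank: int
    worst_projection_error: float

    def __post_init__(self):
        gram = self.basis.conj().T @ self.basis
        if np.abs(gram - np.eye(self.rank)).max() > 1e-10:
            raise ValueError("subspace basis columns are not orthonormal")


@dataclass(frozen=True)
class FitResult:
    """Per-voxel estimates with fit diagnostics."""

    estimates: dict
    residual: float
    converged: bool
    n_iter: int

    @property
    def tissue(self) -> TissuePars:
        e = self.estimates
        return TissuePars(m0s=e["m0s"], R1f=e["R1f"], R2f=e["R2f"],
                          Rx=e["Rx"], R1s=e["R1s"], T2s=e["T2s"])


def build_dictionary(grid_spec: dict, train: PulseTrain,
                     base_tissue: TissuePars | None = None,
                     base_sys: SystemPars | None = None,
                     grid=None) -> Dictionary:
    """Simulate one fingerprint per node of the rectangular grid.

    ``grid_spec`` maps parameter labels to 1-D value arrays; unlisted
    parameters are held at the base values.  Atom order is the row-major
    product of the axes in the given label order.
    """
    if not grid_spec:
        raise ValueError("grid spec must contain at least one axis")
    for lab, vals in grid_spec.items():
        if lab not in LABELS:
            raise ValueError(f"unknown parameter label {lab!r}")
        if len(vals) == 0:
            raise ValueError(f"axis {lab!r} is empty")
        if len(vals) > 1 and not np.all(np.diff(vals) > 0):
            raise ValueError(f"axis {lab!r} must be strictly increasing")
    base_tissue = base_tissue or TissuePars(**{k: _DEFAULT_INIT[k]
                                               for k in LABELS[:6]})
    base_sys = base_sys or SystemPars()
    grid = grid or default_r2sl_grid()
    labels = list(grid_spec)
    pars, atoms = [], []
    for combo in itertools.product(*(np.asarray(grid_spec[l], float)
                                     for l in labels)):
        tissue, sys = base_tissue, base_sys
        for lab, val in zip(labels, combo):
            tissue, sys = set_param(lab, float(val), tissue, sys)
        pars.append((tissue, sys))
        atoms.append(_signal(train, tissue, sys, grid))
    meta = {"labels": labels,
            "train_hash": hash((train.alpha.tobytes(), train.trf.tobytes(),
                                train.tr, train.inv_trf, train.cycle_time))}
    return Dictionary(axes={l: np.asarray(grid_spec[l], float) for l in labels},
                      atoms=np.array(atoms).T, pars=tuple(pars), meta=meta)


def subspace(dictionary: Dictionary, rank: int = 15) -> Subspace:
    """Top-``rank`` left singular vectors of the dictionary matrix."""
    A = dictionary.atoms
    if rank > dictionary.n_atoms:
        raise ValueError(f"rank {rank} exceeds number of atoms "
                         f"{dictionary.n_atoms}")
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if rank > min(A.shape) or s[rank - 1] <= 0:
        raise ValueError(f"rank {rank} exceeds the rank of the dictionary "
                         f"matrix {A.shape}")
    U = U[:, :rank]
    proj = U @ (U.conj().T @ A)
    err = np.linalg.norm(A - proj, axis=0) / np.linalg.norm(A, axis=0)
    return Subspace(basis=U, svals=s[:rank], rank=rank,
                    worst_projection_error=float(err.max()))


def compress(fingerprint, sub: Subspace, normalize: bool = False) -> np.ndarray:
    """Coefficients ``basis^H @ fingerprint``; optionally normalized by the
    first coefficient (removing the complex scale M0)."""
    f = fingerprint.signal if isinstance(fingerprint, Fingerprint) \
        else np.asarray(fingerprint, complex)
    if f.shape[0] != sub.basis.shape[0]:
        raise ValueError("fingerprint length does not match subspace")
    c = sub.basis.conj().T @ f
    if normalize:
        if abs(c[0]) < 1e-12 * np.linalg.norm(c):
            raise DegenerateVoxelError("zero first coefficient")
        c = c / c[0]
    return c


def _prepare_init(init) -> dict:
    vals = dict(_DEFAULT_INIT)
    if init is None:
        return vals
    if isinstance(init, dict):
        vals.update(init)
        return vals
    if isinstance(init, tuple) and len(init) == 2:
        tissue, sys = init
        for lab in LABELS:
            vals[lab] = get_param(lab, tissue, sys)
        return vals
    raise ValueError("init must be None, a dict, or a (tissue, sys) tuple")


def fit_voxel(observation, train: PulseTrain, sub: Subspace | None = None,
              init=None, bounds: dict | None = None, sigma: float | None = None,
              free=LABELS, normalize: bool = False, grid=None,
              max_nfev: int | None = None,
              tied: dict | None = None) -> FitResult:
    """Bounded nonlinear least-squares fit of one observation.

    ``observation`` is a complex fingerprint (length n_pulses) or a
    coefficient vector (length ``sub.rank``).  Real and imaginary parts are
    fitted jointly, the global phase being absorbed into M0 (D16).
    ``tied`` maps a label to another label whose current value it copies
    (e.g. ``{"R1s": "R1f"}`` for a constrained-model fit).
    Non-convergence is flagged on the result, not raised.
    """
    obs = observation.signal if isinstance(observation, Fingerprint) \
        else np.asarray(observation, complex)
    if not np.any(obs != 0):
        raise DegenerateVoxelError("all-zero observation")
    grid = grid or default_r2sl_grid()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    free = tuple(free)
    init_vals = _prepare_init(init)
    expected = sub.rank if sub is not None else train.n_pulses
    if obs.shape[0] != expected:
        raise ValueError(f"observation length {obs.shape[0]} does not match "
                         f"{'subspace rank' if sub else 'train length'} "
                         f"{expected}")
    if normalize:
        if abs(obs[0]) < 1e-12 * np.linalg.norm(obs):
            raise DegenerateVoxelError("zero first coefficient")
        obs = obs / obs[0]

    x0 = np.array([init_vals[lab] for lab in free])
    lo = np.array([bounds[lab][0] for lab in free])
    hi = np.array([bounds[lab][1] for lab in free])
    x0 = np.clip(x0, lo, hi)
    if np.any(lo >= hi):
        raise ValueError("invalid bounds (lower >= upper)")

    tied = dict(tied or {})
    for lab_t in tied:
        if lab_t in free:
            raise ValueError(f"tied parameter {lab_t!r} cannot also be free")

    def model(x):
        tissue = TissuePars(**{k: init_vals[k] for k in LABELS[:6]})
        sys = SystemPars(omega_z=init_vals["omega_z"], b1=init_vals["b1"],
                         M0=complex(init_vals["M0_re"], init_vals["M0_im"]))
        for lab, val in zip(free, x):
            tissue, sys = set_param(lab, float(val), tissue, sys)
        for lab_t, src in tied.items():
            tissue, sys = set_param(lab_t, get_param(src, tissue, sys),
                                    tissue, sys)
        s = _signal(train, tissue, sys, grid)
        if sub is not None:
            s = sub.basis.conj().T @ s
        if normalize:
            s = s / s[0]
        return s

    def residual(x):
        r = model(x) - obs
        return np.concatenate([r.real, r.imag])

    res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        x_scale=np.array([_X_SCALE[lab] for lab in free]),
                        max_nfev=max_nfev)
    estimates = dict(init_vals)
    for lab, val in zip(free, res.x):
        estimates[lab] = float(val)
    for lab_t, src in tied.items():
        estimates[lab_t] = estimates[src]
    return FitResult(estimates=estimates,
                     residual=float(np.linalg.norm(res.fun)),
                     converged=bool(res.status > 0), n_iter=int(res.nfev))


def nearest_atom_init(observation, dictionary: Dictionary,
                      sub: Subspace | None = None) -> dict:
    """Init values from the dictionary atom best matched (up to complex
    scale) to the observation."""
    obs = np.asarray(observation, complex)
    A = dictionary.atoms
    if sub is not None:
        A = sub.basis.conj().T @ A
    A_n = A / np.linalg.norm(A, axis=0)
    score = np.abs(A_n.conj().T @ obs)
    i = int(np.argmax(score))
    tissue, sys = dictionary.pars[i]
    out = {lab: get_param(lab, tissue, sys) for lab in LABELS}
    # complex scale of the best match
    a = A[:, i]
    m0 = (a.conj() @ obs) / (a.conj() @ a) * complex(out["M0_re"],
                                                     out["M0_im"])
    out["M0_re"], out["M0_im"] = m0.real, m0.imag
    return out


def fit_map(image: np.ndarray, mask: np.ndarray, train: PulseTrain,
            sub: Subspace | None = None, init_policy="default",
            dictionary: Dictionary | None = None, free=LABELS,
            normalize: bool = False, grid=None,
            max_nfev: int | None = None):
    """Voxel-by-voxel fit of a (..., C) coefficient/fingerprint image.

    ``init_policy``: "default" (fixed physiologic defaults), "dictionary"
    (nearest dictionary atom per voxel; requires ``dictionary``), or a dict
    of per-parameter init maps.  Voxel order is irrelevant to the result;
    failed voxels are NaN-valued and counted.
    Returns ``(maps, diagnostics)``.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    if image.shape[:-1] != mask.shape:
        raise ValueError("image and mask shapes do not match")
    if init_policy == "dictionary" and dictionary is None:
        raise ValueError("dictionary init policy requires a dictionary")
    grid = grid or default_r2sl_grid()
    maps = {lab: np.full(mask.shape, np.nan) for lab in LABELS}
    resid = np.full(mask.shape, np.nan)
    conv = np.zeros(mask.shape, bool)
    n_failed = 0
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        obs = image[idx]
        if init_policy == "default":
            init = None
        elif init_policy == "dictionary":
            init = nearest_atom_init(obs, dictionary, sub)
        elif isinstance(init_policy, dict):
            init = {lab: float(m[idx]) for lab, m in init_policy.items()}
        else:
            raise ValueError(f"unknown init policy {init_policy!r}")
        try:
            fit = fit_voxel(obs, train, sub, init=init, free=free,
                            normalize=normalize, grid=grid,
                            max_nfev=max_nfev)
        except DegenerateVoxelError:
            n_failed += 1
            continue
        for lab in LABELS:
            maps[lab][idx] = fit.estimates[lab]
        resid[idx] = fit.residual
        conv[idx] = fit.converged
    diagnostics = {"n_failed": n_failed, "residual": resid,
                   "converged": conv,
                   "n_fitted": int(mask.sum()) - n_failed}
    return maps, diagnostics


def fit_monoexp(times, signal) -> float:
    """Rate R of the mono-exponential model ``a + b exp(-R t)``.

    Least-squares over (a, b, R) with a data-driven start; returns R.
    Degenerate constant signals yield R = 0.
    """
    t = np.asarray(times, float)
    y = np.asarray(signal, float)
    if t.size < 3 or y.size != t.size:
        raise ValueError("need at least 3 (time, signal) pairs")
    a0 = y[-1]
    b0 = y[0] - a0
    scale = max(np.abs(y).max(), 1e-30)
    if abs(b0) < 1e-12 * scale and np.ptp(y) < 1e-12 * scale:
        return 0.0
    span = t[-1] - t[0]
    r0 = 1.0 / span if span > 0 else 1.0
    # refine rate init from the signed log-decay when possible
    mid = np.searchsorted(t, t[0] + span / 2)
    if 0 < mid < t.size and (y[mid] - a0) / b0 > 0:
        r_est = -np.log((y[mid] - a0) / b0) / (t[mid] - t[0])
        if np.isfinite(r_est) and r_est > 0:
            r0 = r_est

    def resid(p):
        a, b, r = p
        return a + b * np.exp(-r * t) - y

    res = least_squares(resid, np.array([a0, b0, r0]),
                        bounds=([-np.inf, -np.inf, 0.0],
                                [np.inf, np.inf, np.inf]))
    a, b, r = res.x
    if abs(b) < 1e-9 * scale:
        return 0.0
    return float(r)
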