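"""Apparent-parameter theory of the longitudinal two-pool system.

In the absence of RF irradiation the longitudinal components (zf, zs, 1)
evolve under a 3x3 affine generator whose nonzero eigenvalues define the
apparent relaxation and exchange rates an observer assuming R1s = R1f
would infer.  Taylor expansions of those eigenvalues (and of the apparent
pool size from the eigenvectors) around R1s = R1f give closed-form
approximations; both the exact eigen-route and the expansions are exposed,
together with pool-size normalization conversions and voxel-wise map
generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mt_core import TissuePars

__all__ = [
    "ApparentPars",
    "longitudinal_hamiltonian",
    "exact_apparent_rates",
    "taylor_R1f_a",
    "taylor_Rx_a",
    "taylor_m0s_a",
    "convert_pool_size",
    "apparent_maps",
    "MASK_SENTINEL",
]

MASK_SENTINEL = np.nan
DEFAULT_M0S_THRESHOLD = 0.01  # D9: semi-solid characteristics unreliable below


@dataclass(frozen=True)
class ApparentPars:
    """Apparent parameters of the R1s = R1f constrained interpretation."""

    R1f_a: float
    Rx_a: float
    m0s_a: float
    method: str  # "exact-eigen" | "taylor"


def longitudinal_hamiltonian(tissue: TissuePars) -> np.ndarray:
    """3x3 affine generator of (zf, zs, 1) without RF; last row zero."""
    m0s, m0f = tissue.m0s, tissue.m0f
    R1f, R1s, Rx = tissue.R1f, tissue.R1s, tissue.Rx
    return np.array([
        [-R1f - Rx * m0s, Rx * m0f, m0f * R1f],
        [Rx * m0s, -R1s - Rx * m0f, m0s * R1s],
        [0.0, 0.0, 0.0],
    ])


def exact_apparent_rates(tissue: TissuePars,
                         degenerate_rtol: float = 1e-9) -> tuple[float, float]:
    """Apparent rates from the eigendecomposition of the 2x2 dynamic block.

    Returns ``(R1f_a, Rx_a)``: the absolute values of the smaller and larger
    nonzero eigenvalue (D10).  Near-degenerate eigenvalues are flagged with
    a warning, not an error.
    """
    H = longitudinal_hamiltonian(tissue)
    lam = np.linalg.eigvals(H[:2, :2])
    lam = np.sort(np.abs(lam))
    if lam[1] > 0 and (lam[1] - lam[0]) < degenerate_rtol * lam[1]:
        warnings.warn("near-degenerate longitudinal eigenvalues",
                      RuntimeWarning, stacklevel=2)
    return float(lam[0]), float(lam[1])


def _check_rx(tissue: TissuePars) -> None:
    if tissue.Rx == 0:
        raise ZeroDivisionError("Taylor expansions require Rx > 0")


def taylor_R1f_a(tissue: TissuePars, linear_only: bool = False) -> float:
    """Second-order expansion of the apparent free-pool relaxation rate.

    ``R1f_a ~ R1f + m0s (R1s - R1f) - m0f m0s (R1s - R1f)^2 / Rx``; with
    ``linear_only`` the quadratic term is dropped.
    """
    d = tissue.R1s - tissue.R1f
    lin = tissue.R1f + tissue.m0s * d
    if linear_only:
        return lin
    _check_rx(tissue)
    return lin - tissue.m0f * tissue.m0s * d**2 / tissue.Rx


def taylor_Rx_a(tissue: TissuePars) -> float:
    """Expansion of the apparent exchange (cross-relaxation) rate:
    ``Rx_a ~ (Rx + R1f) + m0f (R1s - R1f) + m0f m0s (R1s - R1f)^2 / Rx``."""
    _check_rx(tissue)
    d = tissue.R1s - tissue.R1f
    return (tissue.Rx + tissue.R1f) + tissue.m0f * d \
        + tissue.m0f * tissue.m0s * d**2 / tissue.Rx


def taylor_m0s_a(tissue: TissuePars) -> float:
    """Expansion of the apparent semi-solid pool size:
    ``m0s_a ~ m0s (1 - 2 m0f (R1s - R1f) / Rx)``."""
    _check_rx(tissue)
    d = tissue.R1s - tissue.R1f
    return tissue.m0s * (1.0 - 2.0 * tissue.m0f * d / tissue.Rx)


def apparent_pars(tissue: TissuePars, method: str = "taylor") -> ApparentPars:
    """Bundle apparent parameters via either route."""
    if method == "taylor":
        return ApparentPars(taylor_R1f_a(tissue), taylor_Rx_a(tissue),
                            taylor_m0s_a(tissue), "taylor")
    if method == "exact-eigen":
        r1fa, rxa = exact_apparent_rates(tissue)
        return ApparentPars(r1fa, rxa, taylor_m0s_a(tissue), "exact-eigen")
    raise ValueError(f"unknown method {method!r}")


def convert_pool_size(value, direction: str = "to_sum_normalized"):
    """Convert between the two pool-size normalizations.

    ``to_sum_normalized``: m0s = m~0s / (1 + m~0s) (input normalized to
    m0f = 1); ``to_free_normalized``: m~0s = m0s / (1 - m0s).  Vectorized.
    """
    v = np.asarray(value, float)
    if direction == "to_sum_normalized":
        if np.any(v < 0):
            raise ValueError("m~0s must be >= 0")
        out = v / (1.0 + v)
    elif direction == "to_free_normalized":
        if np.any((v < 0) | (v >= 1)):
            raise ValueError("m0s must be in [0, 1)")
        out = v / (1.0 - v)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) else out


def apparent_maps(m0s, R1f, R1s, Rx, mask=None,
                  m0s_threshold: float = DEFAULT_M0S_THRESHOLD):
    """Voxel-wise Taylor apparent-parameter maps.

    Arrays must share a common grid; voxels outside ``mask``, with
    ``m0s`` below threshold (D9), or with non-finite inputs are set to NaN.
    Returns ``(R1f_a, Rx_a, m0s_a)`` maps.
    """
    m0s, R1f, R1s, Rx = (np.asarray(a, float) for a in (m0s, R1f, R1s, Rx))
    if not (m0s.shape == R1f.shape == R1s.shape == Rx.shape):
        raise ValueError("parameter maps must share a common shape")
    if mask is None:
        mask = np.ones(m0s.shape, bool)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != m0s.shape:
            raise ValueError("mask shape does not match maps")
    finite = np.isfinite(m0s) & np.isfinite(R1f) & np.isfinite(R1s) \
        & np.isfinite(Rx) & (Rx > 0)
    valid = mask & finite & (m0s >= m0s_threshold)

    m0f = 1.0 - m0s
    d = R1s - R1f
    with np.errstate(divide="ignore", invalid="ignore"):
        r1f_a = R1f + m0s * d - m0f * m0s * d**2 / Rx
        rx_a = (Rx + R1f) + m0f * d + m0f * m0s * d**2 / Rx
        m0s_a = m0s * (1.0 - 2.0 * m0f * d / Rx)
    out = []
    for arr in (r1f_a, rx_a, m0s_a):
        arr = np.where(valid, arr, MASK_SENTINEL)
        out.append(arr)
    return tuple(out)
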