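"""Default tissue-class parameter values for the digital phantom.

White- and gray-matter values are healthy-control ROI means measured with
the unconstrained two-pool MT model (relaxation times converted to rates);
the CSF-like class is an essentially free-water compartment with a
vanishing semi-solid pool.
"""

from .mt_core import TissuePars

# ROI means: m0s [-], T1f [s], T2f [ms], Rx [1/s], T1s [s], T2s [us]
_WM = dict(m0s=0.212, T1f=1.84, T2f_ms=76.9, Rx=13.6, T1s=0.34, T2s_us=12.5)
_GM = dict(m0s=0.098, T1f=2.46, T2f_ms=83.0, Rx=14.0, T1s=0.42, T2s_us=14.4)


def _to_pars(row: dict) -> TissuePars:
    return TissuePars(m0s=row["m0s"], R1f=1.0 / row["T1f"],
                      R2f=1.0 / (row["T2f_ms"] * 1e-3), Rx=row["Rx"],
                      R1s=1.0 / row["T1s"], T2s=row["T2s_us"] * 1e-6)


CLASS_TABLE = {
    # listed inside-out: CSF core, GM shell, WM bulk
    "csf": TissuePars(m0s=0.0, R1f=0.25, R2f=0.5, Rx=5.0, R1s=1.0,
                      T2s=10e-6),
    "gm": _to_pars(_GM),
    "wm": _to_pars(_WM),
}

# ROI standard deviations in the same units, used for optional per-voxel
# jitter of the class values
CLASS_SD = {
    "wm": dict(m0s=0.022, T1f=0.17, T2f=8.3e-3, Rx=1.1, T1s=0.10,
               T2s=1.8e-6),
    "gm": dict(m0s=0.026, T1f=0.56, T2f=15e-3, Rx=3.1, T1s=0.40,
               T2s=3.9e-6),
}
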