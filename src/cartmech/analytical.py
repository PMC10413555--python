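"""Closed-form reference solutions for solver validation.

One-dimensional consolidation of a linear poroelastic column under a
suddenly applied surface stress sigma0 (drained at the loaded surface,
sealed at the base and sides, laterally confined).  With consolidation
coefficient c_v = k (lambda + 2G) and time factor T = c_v t / h^2:

    p(Z, T)/sigma0 = sum_m (2/M_m) sin(M_m Z) exp(-M_m^2 T)
    U(T) = 1 - sum_m (2/M_m^2) exp(-M_m^2 T),   M_m = pi (2m+1)/2

where Z is depth from the drained surface normalised by the column
height h, and U is the consolidation ratio (settlement over the final
drained settlement sigma0 h / (lambda + 2G)).
"""

from __future__ import annotations

import numpy as np

__all__ = ["consolidation_pressure", "consolidation_ratio", "consolidation_coefficient"]


def consolidation_coefficient(k: float, G: float, lam: float) -> float:
    """c_v = k (lambda + 2G) for a laterally confined biphasic column."""
    return k * (lam + 2.0 * G)


def _modes(n_terms: int) -> np.ndarray:
    return (np.pi / 2.0) * (2.0 * np.arange(n_terms) + 1.0)


def consolidation_pressure(z_over_h: float, T, n_terms: int = 300):
    """Excess pore pressure ratio p/sigma0 at normalised depth Z and time factor T."""
    M = _modes(n_terms)
    T = np.atleast_1d(np.asarray(T, dtype=float))[:, None]
    out = (2.0 / M * np.sin(M * z_over_h) * np.exp(-(M**2) * T)).sum(axis=1)
    return out if out.size > 1 else float(out[0])


def consolidation_ratio(T, n_terms: int = 300):
    """Degree of consolidation U(T) = settlement / final drained settlement."""
    M = _modes(n_terms)
    T = np.atleast_1d(np.asarray(T, dtype=float))[:, None]
    out = 1.0 - (2.0 / M**2 * np.exp(-(M**2) * T)).sum(axis=1)
    return out if out.size > 1 else float(out[0])
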