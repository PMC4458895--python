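"""Worm-like chain elasticity (Marko-Siggia interpolation).

The entropic force of a WLC of contour length ``Lc`` and persistence
length ``p`` held at end-to-end extension ``x``:

    F(x) = (kBT/p) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

which vanishes at x=0 and diverges as x -> Lc.  This interpolation (no
higher-order correction terms) is used consistently by the force-trace
generator and the segment-fitting analysis.
"""

from __future__ import annotations

import numpy as np

from .constants import kbt

DEFAULT_PERSISTENCE_NM = 0.4


def wlc_force(x, lc: float, p: float = DEFAULT_PERSISTENCE_NM,
              temperature_k: float = 298.0):
    """WLC force (pN) at extension ``x`` (nm). Accepts scalars or arrays.

    Raises ValueError for x < 0 or x >= Lc (the model diverges there).
    """
    x = np.asarray(x, dtype=float)
    if lc <= 0 or p <= 0:
        raise ValueError("Lc and p must be positive")
    if np.any(x < 0) or np.any(x >= lc):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    u = x / lc
    f = (kbt(temperature_k) / p) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
    return float(f) if f.ndim == 0 else f


def wlc_stiffness(x, lc: float, p: float = DEFAULT_PERSISTENCE_NM,
                  temperature_k: float = 298.0):
    """dF/dx (pN/nm) of the Marko-Siggia force at extension x."""
    x = np.asarray(x, dtype=float)
    u = x / lc
    k = (kbt(temperature_k) / (p * lc)) * (0.5 / (1.0 - u) ** 3 + 1.0)
    return float(k) if k.ndim == 0 else k


def wlc_extension(force, lc: float, p: float = DEFAULT_PERSISTENCE_NM,
                  temperature_k: float = 298.0, tol: float = 1e-12):
    """Invert the Marko-Siggia relation: extension (nm) at a given force.

    Vectorized bisection on [0, Lc); monotonicity of F(x) guarantees a
    unique root for any force >= 0.
    """
    f_target = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f_target < 0):
        raise ValueError("force must be non-negative")
    lo = np.zeros_like(f_target)
    hi = np.full_like(f_target, lc * (1.0 - 1e-12))
    c = kbt(temperature_k) / p
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        u = mid / lc
        f_mid = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        high = f_mid > f_target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    return float(out[0]) if np.isscalar(force) or np.ndim(force) == 0 else out
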