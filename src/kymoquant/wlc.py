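"""Worm-like-chain entropic elasticity.

Marko–Siggia interpolation formula for the force–extension relation of a
semiflexible polymer,

    F(z) = (kBT / P) * [ 1 / (4 (1 - z)^2) - 1/4 + z ],   z = x / L,

with persistence length P and contour length L.  Enthalpic stretching is
ignored; the formula is used below ~30 pN where it is a good approximation
for double-stranded DNA.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

KB = 1.380649e-23  # J/K
T_DEFAULT = 298.0  # K


def kbt_pn_nm(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kBT in pN·nm."""
    return KB * temperature * 1e21


def wlc_force(extension_um, contour_length_um: float, persistence_length_nm: float = 50.0,
              temperature: float = T_DEFAULT):
    """Force (pN) at a given end-to-end extension (µm).

    Vectorized over ``extension_um``.  Extensions must lie in
    [0, contour_length_um); values at or beyond the contour length are out
    of model and returned as ``inf``.
    """
    z = np.asarray(extension_um, dtype=float) / contour_length_um
    if np.any(z < 0):
        raise ValueError("extension must be nonnegative")
    c = kbt_pn_nm(temperature) / persistence_length_nm
    with np.errstate(divide="ignore"):
        f = c * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    f = np.where(z >= 1.0, np.inf, f)
    return f if f.ndim else float(f)


def wlc_extension(force_pn, contour_length_um: float, persistence_length_nm: float = 50.0,
                  temperature: float = T_DEFAULT):
    """End-to-end extension (µm) at a given force (pN); inverse of :func:`wlc_force`."""
    forces = np.atleast_1d(np.asarray(force_pn, dtype=float))
    if np.any(forces < 0):
        raise ValueError("force must be nonnegative")
    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        if f == 0:
            out[i] = 0.0
            continue
        out[i] = brentq(
            lambda z: wlc_force(z * contour_length_um, contour_length_um,
                                persistence_length_nm, temperature) - f,
            0.0, 1.0 - 1e-12, xtol=1e-12,
        ) * contour_length_um
    return out if np.ndim(force_pn) else float(out[0])
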