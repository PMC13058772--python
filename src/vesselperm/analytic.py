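"""Closed-form diffusion solutions used for calibration and solver validation.

In the wall-limited transport regime the tracer concentration at the vessel
wall stays far below the lumen concentration, so the transmural flux is nearly
constant at ``J0 = P * C0``.  Half-space diffusion under a constant surface
flux has the classical solution

    C(x, t) = (J0 / D) * [ sqrt(4 D t / pi) * exp(-x^2 / (4 D t))
                           - x * erfc(x / sqrt(4 D t)) ]

which bounds the membrane-limited (Robin boundary) solution from above and is
nearly equal to it when ``P * sqrt(t / (pi * D)) << 1``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc, erfcx

__all__ = ["constant_flux_profile", "robin_wall_profile", "wall_limited_parameter"]


def constant_flux_profile(
    x: np.ndarray | float, t: float, D: float, J0: float
) -> np.ndarray | float:
    """Concentration in a half-space fed by a constant surface flux.

    Parameters
    ----------
    x
        Distance from the releasing surface (µm); scalar or array, >= 0.
    t
        Elapsed time (min), > 0.
    D
        Diffusivity (µm²/min).
    J0
        Surface flux (mM·µm/min), e.g. ``P * C0`` for a wall-limited vessel.

    Returns
    -------
    Concentration in mM, same shape as ``x``.
    """
    if t <= 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    s = np.sqrt(4.0 * D * t)
    out = (J0 / D) * (s / np.sqrt(np.pi) * np.exp(-((x / s) ** 2)) - x * erfc(x / s))
    return out if out.ndim else float(out)


def robin_wall_profile(
    x: np.ndarray | float, t: float, D: float, P: float, C0: float
) -> np.ndarray | float:
    """Exact half-space solution for a membrane (Robin) boundary.

    For ``dC/dt = D C''`` on x > 0 with ``-D C'(0) = P (C0 - C(0))`` and
    zero initial condition (Carslaw & Jaeger, surface-conductance case):

        C(x, t) / C0 = erfc(xi) - exp(k x + k^2 D t) * erfc(xi + z)

    with ``xi = x / sqrt(4 D t)``, ``k = P / D``, ``z = k * sqrt(D t)``.
    Evaluated via the scaled complement ``erfcx`` so the exponential factor
    never overflows:  ``exp(k x + z^2) erfc(xi + z) = erfcx(xi + z) *
    exp(-xi^2)``.

    This is what :func:`constant_flux_profile` approximates from above in
    the wall-limited regime; the relative wall deficit between the two is
    ``~ z sqrt(pi) / 2``.
    """
    if t <= 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    xi = x / np.sqrt(4.0 * D * t)
    z = (P / D) * np.sqrt(D * t)
    out = C0 * (erfc(xi) - erfcx(xi + z) * np.exp(-(xi**2)))
    out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


def wall_limited_parameter(P: float, t: float, D: float) -> float:
    """Dimensionless group ``P * sqrt(t / (pi * D))``.

    Half its doubled value, ``2 P sqrt(t/(pi D))``, is the relative wall
    depletion ``C_wall / C0`` predicted by the constant-flux solution; values
    well below 1 indicate the membrane, not bulk diffusion, limits release.
    """
    return P * np.sqrt(t / (np.pi * D))
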