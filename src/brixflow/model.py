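"""Brix two-compartment pharmacokinetic model of contrast-agent kinetics.

The model describes the relative signal enhancement of a tissue voxel after a
bolus of low-molecular-weight contrast agent.  The agent exchanges between
blood plasma and the extracellular extravascular space (EES) at rate ``k_ep``
(per minute) and is eliminated from plasma at rate ``k_el`` (per minute); the
dimensionless amplitude ``A`` is related to the size of the EES::

    RSI(t) = A * k_ep / (k_el - k_ep) * (exp(-k_ep * t) - exp(-k_el * t))

with the analytic limit ``A * k_ep * t * exp(-k_ep * t)`` on the diagonal
``k_ep == k_el``.  Time is measured in minutes from the (mid-)bolus.
"""

from __future__ import annotations

import numpy as np

__all__ = ["brix_rsi", "brix_peak_time"]

# relative separation of the rate constants below which the degenerate
# (k_ep == k_el) closed form is used
_DIAGONAL_RTOL = 1e-9


def _validate(t, A, k_ep, k_el) -> None:
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    for name, value in (("A", A), ("k_ep", k_ep), ("k_el", k_el)):
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def brix_rsi(t, A, k_ep, k_el):
    """Relative signal enhancement at time ``t`` (minutes post-bolus).

    Parameters
    ----------
    t : array_like
        Time in minutes, ``t >= 0``.
    A : float
        Dimensionless amplitude, ``A >= 0``.
    k_ep, k_el : float
        Plasma/EES exchange rate and plasma elimination rate (1/min),
        both ``>= 0``.

    Returns
    -------
    ndarray or float
        Enhancement, finite for all valid inputs and continuous across the
        ``k_ep == k_el`` diagonal.
    """
    _validate(t, A, k_ep, k_el)
    t = np.asarray(t, dtype=float)
    # near the diagonal the general form cancels catastrophically; there the
    # factorization A*k_ep*t*E1*phi(x), x = (k_el-k_ep)*t, phi = (1-e^-x)/x
    # is evaluated through a 4-term Taylor series of phi (error O(x^4))
    x = (k_el - k_ep) * t
    E1 = np.exp(-k_ep * t)
    phi_taylor = 1.0 - x / 2.0 + x * x / 6.0 - x**3 / 24.0
    limit_form = A * k_ep * t * E1 * phi_taylor
    if k_el == k_ep:
        out = limit_form
    else:
        general = A * k_ep / (k_el - k_ep) * (E1 - np.exp(-k_el * t))
        out = np.where(np.abs(x) < 1e-4, limit_form, general)
    return out if out.shape else float(out)


def brix_peak_time(k_ep: float, k_el: float) -> float:
    """Time of maximum enhancement, ``t* = ln(k_ep/k_el) / (k_ep - k_el)``.

    For ``k_ep == k_el`` the limit is ``1 / k_ep``.  Requires both rates
    strictly positive.
    """
    if k_ep <= 0 or k_el <= 0:
        raise ValueError("rate constants must be positive")
    scale = max(k_ep, k_el)
    if abs(k_el - k_ep) <= _DIAGONAL_RTOL * scale:
        return 1.0 / k_ep
    return float(np.log(k_ep / k_el) / (k_ep - k_el))
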