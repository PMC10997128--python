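"""Plackett (global odds ratio) joint distribution for a pair of binary outcomes.

For two Bernoulli margins ``pi1 = P(Y1 = 1)`` and ``pi2 = P(Y2 = 1)`` and a
cross-product ratio ``psi = p11 * p00 / (p10 * p01)``, there is a unique joint
law over the four cells (1,1), (1,0), (0,1), (0,0).  Its (1,1) cell solves a
quadratic in the margins and psi:

    psi != 1:  p11 = [S - sqrt(S^2 - 4 psi (psi - 1) pi1 pi2)] / (2 (psi - 1)),
               S = 1 + (pi1 + pi2)(psi - 1)
    psi == 1:  p11 = pi1 * pi2

The implementation rationalises the root so the psi -> 1 limit needs no branch:

    p11 = 2 psi pi1 pi2 / (S + sqrt(S^2 - 4 psi (psi - 1) pi1 pi2))

which is algebraically identical for psi != 1 and equals pi1*pi2 at psi = 1.
This family is the association structure of the bivariate binary logistic
regression model: two marginal logits plus one dependence odds ratio.
"""

from __future__ import annotations

import numpy as np

__all__ = ["joint_cell_probabilities", "joint_cell_derivatives"]


def _validate_psi(psi) -> None:
    if not np.all(np.asarray(psi) > 0):
        raise ValueError("association odds ratio psi must be > 0")


def joint_cell_probabilities(pi1, pi2, psi):
    """Joint cell probabilities (p11, p10, p01, p00) with margins and odds ratio.

    Parameters
    ----------
    pi1, pi2 : float or ndarray
        Marginal success probabilities in (0, 1); broadcast against each other.
    psi : float or ndarray
        Cross-product (global odds) ratio, > 0.  ``psi = 1`` is independence.

    Returns
    -------
    tuple of ndarray (or floats for scalar input)
        ``(p11, p10, p01, p00)``; nonnegative, summing to one, with
        ``p11 + p10 = pi1`` and ``p11 + p01 = pi2``, and p11 inside the
        Frechet bounds ``[max(0, pi1 + pi2 - 1), min(pi1, pi2)]``.
    """
    _validate_psi(psi)
    scalar = np.isscalar(pi1) and np.isscalar(pi2) and np.isscalar(psi)
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    psi = np.asarray(psi, dtype=float)

    delta = psi - 1.0
    s = 1.0 + (pi1 + pi2) * delta
    disc = s * s - 4.0 * psi * delta * pi1 * pi2
    # disc >= (1 - (pi1+pi2) + ...)^2 analytically; guard rounding only.
    disc = np.maximum(disc, 0.0)
    p11 = 2.0 * psi * pi1 * pi2 / (s + np.sqrt(disc))

    # clamp to the Frechet box against last-bit rounding
    lo = np.maximum(0.0, pi1 + pi2 - 1.0)
    hi = np.minimum(pi1, pi2)
    p11 = np.clip(p11, lo, hi)

    p10 = pi1 - p11
    p01 = pi2 - p11
    p00 = 1.0 - pi1 - pi2 + p11
    if scalar:
        return float(p11), float(p10), float(p01), float(p00)
    return p11, p10, p01, p00


def joint_cell_derivatives(pi1, pi2, psi):
    """Partial derivatives of p11 with respect to (pi1, pi2, psi).

    Obtained by implicit differentiation of the defining identity
    ``p11 p00 = psi p10 p01``:

        d p11 / d pi1 = (p11 + psi p01) / D
        d p11 / d pi2 = (p11 + psi p10) / D
        d p11 / d psi =  p10 p01 / D,      D = p11 + p00 + psi (p10 + p01)

    Returns ``(p_cells, dp11_dpi1, dp11_dpi2, dp11_dpsi)`` where ``p_cells``
    is the tuple from :func:`joint_cell_probabilities`.
    """
    p11, p10, p01, p00 = joint_cell_probabilities(pi1, pi2, psi)
    d = p11 + p00 + np.asarray(psi) * (p10 + p01)
    dp11_dpi1 = (p11 + psi * p01) / d
    dp11_dpi2 = (p11 + psi * p10) / d
    dp11_dpsi = p10 * p01 / d
    return (p11, p10, p01, p00), dp11_dpi1, dp11_dpi2, dp11_dpsi
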