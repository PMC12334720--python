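"""Circular statistics: mean direction, resultant length, Watson-Williams test.

Angles are radians on (-pi, pi]. The Watson-Williams test is the parametric
circular analog of a one-way ANOVA on mean directions; it assumes von-Mises
samples with a common, adequately large concentration (the usual guidance is
a mean resultant length above ~0.45), and applies the standard correction
factor 1 + 3/(8*kappa) estimated from the pooled within-group resultant.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.stats as st


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction of angles (radians), via the resultant vector."""
    angles = np.asarray(angles, float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    return float(np.angle(np.mean(np.exp(1j * angles))))


def resultant_length(angles: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]; 1 = perfectly concentrated."""
    angles = np.asarray(angles, float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    return float(np.abs(np.mean(np.exp(1j * angles))))


def circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed smallest angular difference a - b, wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def vonmises_kappa_mle(r: float) -> float:
    """Maximum-likelihood concentration for a mean resultant length r.

    Standard piecewise approximation (accurate to ~1e-3 over [0, 1)).
    """
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1 / (r ** 3 - 4 * r ** 2 + 3 * r)


def watson_williams(*groups: np.ndarray) -> tuple[float, float]:
    """Watson-Williams multi-sample test for equal mean directions.

    Returns (F, p) with F on (k-1, N-k) degrees of freedom after the
    concentration correction. Warns when the pooled resultant length is too
    small for the test's assumptions to hold.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 angles")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())
    Ris = np.array([g.size * resultant_length(g) for g in groups])
    all_angles = np.concatenate(groups)
    R = N * resultant_length(all_angles)
    rw = Ris.sum() / N
    if rw < 0.45:
        warnings.warn(
            f"pooled resultant length {rw:.2f} < 0.45; Watson-Williams "
            "assumptions violated, result unreliable", stacklevel=2)
    kappa = vonmises_kappa_mle(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else np.nan
    num = (N - k) * (Ris.sum() - R)
    den = (k - 1) * (N - Ris.sum())
    if den <= 0:
        return float("inf"), 0.0
    F = correction * num / den
    F = max(F, 0.0)
    p = float(st.f.sf(F, k - 1, N - k))
    return float(F), p
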