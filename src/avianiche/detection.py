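"""Half-normal point-transect detection math.

Detection of an individual at radial distance ``r`` from a point-count
station follows the half-normal key ``g(r) = exp(-r^2 / (2 sigma^2))``.
The detection scale ``sigma`` (metres) is modelled on the log scale as a
species intercept plus a shared vegetation-category offset:

    log(sigma_js) = alpha_s + gamma[veg_j]

Because point-transect survey area grows with radius, the distance of an
individual available for detection has triangular density ``2 r / w^2`` on
``[0, w]``.  The probability that an individual falls in distance class
``d`` with breaks ``(h_{d-1}, h_d]`` AND is detected is

    p_d = (2 / w^2) * Integral_{h_{d-1}}^{h_d} r g(r) dr
        = (2 sigma^2 / w^2) * [exp(-h_{d-1}^2/(2 sigma^2))
                               - exp(-h_d^2/(2 sigma^2))]

which this module evaluates in closed form; the integral over the whole
circle ``[0, w]`` is the overall detection probability ``p = sum_d p_d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "half_normal",
    "detection_scale",
    "cell_probabilities",
    "CellProbabilities",
    "DetectionParams",
]


@dataclass(frozen=True)
class DetectionParams:
    """Log-scale detection parameters: per-species intercepts and shared
    vegetation offsets (reference category fixed at 0)."""

    alpha_s: np.ndarray  # (S,)
    gamma: np.ndarray    # (V,), gamma[0] == 0

    def __post_init__(self):
        object.__setattr__(self, "alpha_s", np.atleast_1d(np.asarray(self.alpha_s, float)))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, float)))
        if self.gamma[0] != 0.0:
            raise ValueError("reference vegetation category must have gamma = 0")

    def sigma(self, veg) -> np.ndarray:
        """Detection scale sigma (metres) per site x species, shape (J, S)."""
        return detection_scale(self.alpha_s[None, :], self.gamma, np.asarray(veg)[:, None])


def half_normal(r, sigma):
    """Half-normal detection probability ``g(r) = exp(-r^2 / (2 sigma^2))``.

    Parameters
    ----------
    r : float or array_like
        Radial distance(s) from the survey point, metres. Must be >= 0.
    sigma : float or array_like
        Detection scale, metres. Must be > 0.
    """
    r = np.asarray(r, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("detection scale sigma must be > 0")
    if np.any(r < 0):
        raise ValueError("distance r must be >= 0")
    out = np.exp(-(r**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def detection_scale(alpha_s, gamma, veg):
    """Detection scale ``sigma = exp(alpha_s + gamma[veg])`` in metres.

    Parameters
    ----------
    alpha_s : float or array_like
        Species log-scale intercept(s).
    gamma : array_like
        Per-vegetation-category log-scale offsets; ``gamma[0]`` is the
        reference category and must be 0 by the coding convention.
    veg : int or array_like of int
        Vegetation category index (0-based) per site.
    """
    gamma = np.asarray(gamma, dtype=float)
    veg = np.asarray(veg)
    if np.any(veg < 0) or np.any(veg >= gamma.shape[0]):
        raise KeyError(f"unknown vegetation category in {np.unique(veg)!r}")
    out = np.exp(np.asarray(alpha_s, dtype=float) + gamma[veg])
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CellProbabilities:
    """Distance-class detection probabilities for one (site, species) cell.

    Attributes
    ----------
    p_d : ndarray
        Per-class probability of "present in class d and detected"
        (..., D); includes the triangular area weighting.
    p : ndarray or float
        Overall detection probability, ``sum_d p_d``.
    p_cond : ndarray
        Conditional multinomial cell probabilities ``p_d / p``; rows sum
        to 1.
    """

    p_d: np.ndarray
    p: np.ndarray
    p_cond: np.ndarray


def cell_probabilities(sigma, breaks, w) -> CellProbabilities:
    """Closed-form distance-class probabilities for a half-normal key.

    Parameters
    ----------
    sigma : float or array_like
        Detection scale(s), metres; broadcast against distance classes.
    breaks : array_like
        Strictly increasing class breaks starting at 0 and ending at
        ``w``, e.g. ``(0, 10, 20, 50, 100)``.
    w : float
        Maximum observation radius, metres.

    Returns
    -------
    CellProbabilities
        With ``p_d`` of shape ``sigma.shape + (D,)``.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or breaks.size < 2:
        raise ValueError("breaks must be a 1-d vector with >= 2 entries")
    if breaks[0] != 0 or not np.isclose(breaks[-1], w):
        raise ValueError("breaks must start at 0 and end at w")
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("detection scale sigma must be > 0")

    s2 = sigma[..., None] ** 2
    # p_d = (2 s2/w^2) [exp(-h_{d-1}^2/2s2) - exp(-h_d^2/2s2)]; the expm1
    # form avoids catastrophic cancellation when sigma >> w
    lo, hi = breaks[:-1], breaks[1:]
    p_d = (
        (2.0 * s2 / w**2)
        * np.exp(-(lo**2) / (2.0 * s2))
        * (-np.expm1(-(hi**2 - lo**2) / (2.0 * s2)))
    )
    p = p_d.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cond = np.where(p[..., None] > 0, p_d / p[..., None], np.nan)
    return CellProbabilities(p_d=p_d, p=p, p_cond=p_cond)
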