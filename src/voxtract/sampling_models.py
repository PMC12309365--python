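"""Geometric probability of a linear structure surviving sectioning intact.

A thin elongated structure (e.g. a membrane intrusion of length L) inside a
section of thickness d is modeled as Buffon's needle: dropped with uniform
random offset and orientation onto parallel planes spaced d apart, the
structure is observed intact exactly when it crosses no plane.  The intact
probability is therefore 1 minus the classical crossing probability, which
for an average intrusion length of 367.5 nm in a 100-nm section is below 0.1 —
one reason such structures evade detection in thin-section imaging while
being readily captured by deep volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NeedleModel", "p_cross", "p_intact", "p_half_intact", "p_intact_mc",
           "intact_curve"]


@dataclass(frozen=True)
class NeedleModel:
    """Needle (structure) length L and line spacing (section depth) d, in nm."""

    length_nm: float
    spacing_nm: float

    def __post_init__(self):
        if self.length_nm < 0:
            raise ValueError("needle length must be >= 0")
        if self.spacing_nm <= 0:
            raise ValueError("line spacing must be > 0")


def p_cross(model: NeedleModel) -> float:
    """Classical Buffon crossing probability for needle length L, spacing d.

    Short needle (L <= d): 2L / (pi d).
    Long needle (L > d):  (2/pi) [ (L/d)(1 - sqrt(1 - (d/L)^2)) + pi/2 - arcsin(d/L) ].
    """
    L, d = model.length_nm, model.spacing_nm
    if L == 0:
        return 0.0
    r = L / d
    if r <= 1.0:
        return 2.0 * r / np.pi
    q = d / L
    return (2.0 / np.pi) * (r * (1.0 - np.sqrt(1.0 - q * q)) + np.pi / 2.0 - np.arcsin(q))


def p_intact(model: NeedleModel) -> float:
    """Probability the structure lies fully within one section: 1 - p_cross."""
    return 1.0 - p_cross(model)


def p_half_intact(model: NeedleModel) -> float:
    """Probability of capturing at least half the structure in one section.

    Evaluated as the intact probability of a needle of half length, the
    dashed-curve construction: observing only half an intrusion is what makes
    it indistinguishable from a shallow indentation or inclusion.
    """
    return p_intact(NeedleModel(model.length_nm / 2.0, model.spacing_nm))


def p_intact_mc(model: NeedleModel, n: int = 1_000_000, seed: int = 0):
    """Monte-Carlo estimate of the intact probability (independent of the closed form).

    Drops ``n`` needles with center offset uniform in [0, d) and planar
    orientation angle uniform in [0, pi/2); the needle crosses a line when its
    projected half-extent (L/2) sin(theta) spans the distance to the nearest
    line.  Returns (estimate, standard error).
    """
    if n < 1:
        raise ValueError("need at least one trial")
    L, d = model.length_nm, model.spacing_nm
    if L == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, np.pi / 2.0, size=n)
    center = rng.uniform(0.0, d, size=n)
    to_nearest = np.minimum(center, d - center)
    crossed = (L / 2.0) * np.sin(theta) >= to_nearest
    p_hat = 1.0 - crossed.mean()
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return float(p_hat), se


def intact_curve(length_nm: float, spacing_nm) -> pd.DataFrame:
    """Intact and half-intact probabilities across a range of section depths.

    Mirrors the solid/dashed detection-probability curves: one row per
    spacing value d with columns p_intact and p_half_intact.
    """
    rows = [
        {
            "spacing_nm": float(d),
            "p_intact": p_intact(NeedleModel(length_nm, float(d))),
            "p_half_intact": p_half_intact(NeedleModel(length_nm, float(d))),
        }
        for d in np.atleast_1d(spacing_nm)
    ]
    return pd.DataFrame(rows)
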