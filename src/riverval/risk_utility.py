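"""Certainty-equivalent utilities and risk-attitude classification.

Risk attitude is elicited at the root objective with 50–50 lotteries: the
certainty equivalent (CE) x_p is the sure root value judged equivalent to a
lottery whose expected value is p.  A CE below the expected value means the
expert gives up expected value for certainty — risk aversion — and bends
the utility curve above the diagonal (concave); a CE above it means risk
proneness (convex).  The utility function interpolates the anchor points
(0,0), (x_0.25, 0.25), (x_0.5, 0.5), (x_0.75, 0.75), (1,1) piecewise
linearly, so each elicited anchor is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq


class RiskError(ValueError):
    pass


@dataclass(frozen=True)
class CEPoints:
    """Certainty equivalents for the 25%, 50% and 75% lotteries.

    Each lies strictly inside (0, 1) and the three must be strictly
    increasing; a non-monotone sequence signals inconsistent elicitation.
    """

    x25: float
    x50: float
    x75: float
    expert: str = ""

    def __post_init__(self):
        pts = (self.x25, self.x50, self.x75)
        if not all(0 < p < 1 for p in pts):
            raise RiskError(f"CE points must lie in (0, 1): {pts}")
        if not self.x25 < self.x50 < self.x75:
            raise RiskError(
                f"inconsistent elicitation: CE points not strictly increasing {pts}"
            )


@dataclass
class UtilityFunction:
    """Monotone piecewise-linear value → utility transform on [0, 1]."""

    values: np.ndarray
    utilities: np.ndarray
    expert: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.utilities = np.asarray(self.utilities, dtype=float)
        if self.values.shape != self.utilities.shape or self.values.size < 2:
            raise RiskError("need matching (value, utility) anchor arrays")
        if self.values[0] != 0 or self.values[-1] != 1:
            raise RiskError("utility anchors must span values 0..1")
        if self.utilities[0] != 0 or self.utilities[-1] != 1:
            raise RiskError("utility endpoints are fixed at (0,0) and (1,1)")
        if np.any(np.diff(self.values) <= 0) or np.any(np.diff(self.utilities) < 0):
            raise RiskError("utility anchors must be monotone increasing")

    def __call__(self, value: float) -> float:
        if not 0 <= value <= 1:
            raise RiskError(f"value {value} outside [0, 1]")
        return float(np.interp(value, self.values, self.utilities))

    @property
    def anchors(self) -> list[tuple[float, float]]:
        return list(zip(self.values.tolist(), self.utilities.tolist()))


IDENTITY_UTILITY = UtilityFunction(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                                   expert="risk-neutral")


def utility_from_ce(
    ce: CEPoints, extra_points: Sequence[tuple[float, float]] = ()
) -> UtilityFunction:
    """Piecewise-linear utility through the five CE anchor points.

    ``u(x_p) = p`` exactly for each elicited p.  ``extra_points`` are
    consistency-check probes (value, utility) elicited between anchors; they
    are merged in and must preserve monotonicity, otherwise the elicitation
    was inconsistent and this raises.
    """
    pts = {0.0: 0.0, ce.x25: 0.25, ce.x50: 0.5, ce.x75: 0.75, 1.0: 1.0}
    for value, utility in extra_points:
        pts[float(value)] = float(utility)
    values = np.array(sorted(pts))
    utilities = np.array([pts[v] for v in values])
    if np.any(np.diff(utilities) < 0):
        raise RiskError("consistency check failed: utilities not monotone in value")
    return UtilityFunction(values, utilities, expert=ce.expert)


def classify_risk(u: UtilityFunction, at: float, tol: float = 0.02) -> str:
    """Risk attitude read off the utility curve at a probe value.

    ``averse`` when the curve lies above the diagonal by more than ``tol``
    (equivalently the CE is below the lottery's expected value), ``prone``
    when below it, ``neutral`` otherwise.  The default tolerance absorbs
    the granularity of elicitation on the value scale.
    """
    if not 0 < at < 1:
        raise RiskError("probe point must lie strictly inside (0, 1)")
    gap = u(at) - at
    if gap > tol:
        return "averse"
    if gap < -tol:
        return "prone"
    return "neutral"


def apply_risk(root_value: float, u: UtilityFunction | None = None) -> float:
    """Root utility: the utility curve evaluated at the rolled-up root value.

    With no utility supplied the identity is used — the risk-neutrality
    simplification, left explicit so callers can flag it.
    """
    if not 0 <= root_value <= 1:
        raise RiskError(f"root value {root_value} outside [0, 1]")
    if u is None:
        u = IDENTITY_UTILITY
    return u(root_value)


def certainty_equivalent(u: UtilityFunction, p: float) -> float:
    """Inverse utility: the sure value whose utility equals ``p``."""
    if not 0 <= p <= 1:
        raise RiskError(f"target utility {p} outside [0, 1]")
    return float(np.interp(p, u.utilities, u.values))


def fit_exponential(u: UtilityFunction) -> tuple[float, float]:
    """Diagnostic constant-risk-aversion fit u(x) ≈ (1−e^{−cx})/(1−e^{−c}).

    Returns (c, max_abs_residual) where c > 0 indicates aversion and c < 0
    proneness; offered as a smooth summary of the elicited anchors only —
    assessment always uses the piecewise-linear interpolant.
    """
    inner = [(v, t) for v, t in u.anchors if 0 < v < 1]
    if not inner:
        return 0.0, 0.0

    def resid(c: float) -> float:
        if abs(c) < 1e-9:
            return float(sum(t - v for v, t in inner))
        return float(sum(t - (1 - np.exp(-c * v)) / (1 - np.exp(-c)) for v, t in inner))

    lo, hi = -50.0, 50.0
    if resid(lo) * resid(hi) > 0:
        c = lo if abs(resid(lo)) < abs(resid(hi)) else hi
    else:
        c = float(brentq(resid, lo, hi, xtol=1e-10))
    if abs(c) < 1e-9:
        fitted = {v: v for v, _ in inner}
    else:
        fitted = {v: (1 - np.exp(-c * v)) / (1 - np.exp(-c)) for v, _ in inner}
    err = max(abs(t - fitted[v]) for v, t in inner)
    return c, float(err)
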