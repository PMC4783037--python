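"""Single-attribute value functions on the common [0, 1] scale.

A value function maps an attribute's natural scale (individuals, °C,
m³/year, quality classes ...) to a preference value between 0 (worst
possible) and 1 (best possible).  Functions are piecewise linear through the
elicited anchor points; that reproduces every elicited (level, value) pair
exactly and is monotone between anchors by construction.  Unimodal
attributes (e.g. in-stream respiration, optimal at an intermediate rate)
carry two monotone limbs that normally share the peak level.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: default grid of value levels addressed during bisection elicitation
ELICITATION_GRID = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)


class ValueFunctionError(ValueError):
    pass


@dataclass
class Limb:
    """One monotone piece: anchor levels ``x`` (strictly ordered) and their
    values ``v`` running from 0 at the limb's worst end to 1 at its best."""

    x: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.size != self.v.size or self.x.size < 2:
            raise ValueFunctionError("a limb needs >= 2 (level, value) points")
        dx = np.diff(self.x)
        if not (np.all(dx > 0) or np.all(dx < 0)):
            raise ValueFunctionError("limb levels must be strictly ordered")
        if np.any(self.v < 0) or np.any(self.v > 1):
            raise ValueFunctionError("values must lie in [0, 1]")
        dv = np.diff(self.v)
        if not (np.all(dv >= 0) or np.all(dv <= 0)):
            raise ValueFunctionError("limb values must be monotone in level")

    def _ascending(self) -> tuple[np.ndarray, np.ndarray]:
        if self.x[0] < self.x[-1]:
            return self.x, self.v
        return self.x[::-1], self.v[::-1]

    @property
    def lo(self) -> float:
        return float(min(self.x[0], self.x[-1]))

    @property
    def hi(self) -> float:
        return float(max(self.x[0], self.x[-1]))

    def contains(self, x: float, tol: float = 1e-12) -> bool:
        return self.lo - tol <= x <= self.hi + tol

    def evaluate(self, x: float) -> float:
        xs, vs = self._ascending()
        return float(np.interp(x, xs, vs))

    def invert(self, v: float) -> float:
        xs, vs = self._ascending()
        if vs[0] > vs[-1]:  # value decreases with x on this limb
            return float(np.interp(v, vs[::-1], xs[::-1]))
        return float(np.interp(v, vs, xs))


@dataclass
class ValueFunction:
    """Piecewise mapping from attribute level to value in [0, 1].

    ``kind`` is ``continuous`` or ``discrete``; discrete functions map each
    admissible level to exactly one value via ``table``.  Continuous
    functions hold one limb (monotone) or two (unimodal).
    """

    attribute: str
    source: str = "expert"
    limbs: list[Limb] = field(default_factory=list)
    table: dict[float, float] | None = None
    kind: str = "continuous"
    flagged: bool = False

    @property
    def orientation(self) -> str:
        if self.kind == "discrete":
            return "discrete"
        if len(self.limbs) == 2:
            return "unimodal"
        limb = self.limbs[0]
        inc_x = limb.x[-1] > limb.x[0]
        inc_v = limb.v[-1] > limb.v[0]
        return "increasing" if inc_x == inc_v else "decreasing"

    @property
    def monotone(self) -> bool:
        return self.kind == "continuous" and len(self.limbs) == 1

    def domain(self) -> list[tuple[float, float]]:
        return [(l.lo, l.hi) for l in self.limbs]


def evaluate(vf: ValueFunction, x: float) -> float:
    """Value of the function at attribute level ``x``.

    Linear interpolation between the bracketing anchor points; elicited
    anchors (including the endpoints, returning exactly 0 or 1) are
    reproduced exactly.  Raises for out-of-range levels and for discrete
    levels that are not admissible.
    """
    if vf.kind == "discrete":
        for level, value in vf.table.items():
            if math.isclose(level, x, rel_tol=0, abs_tol=1e-9):
                return float(value)
        raise ValueFunctionError(
            f"{vf.attribute}: {x!r} is not an admissible discrete level"
        )
    for limb in vf.limbs:
        if limb.contains(x):
            return limb.evaluate(x)
    raise ValueFunctionError(
        f"{vf.attribute}: level {x!r} outside declared range {vf.domain()}"
    )


def invert(vf: ValueFunction, v: float, limb: int | None = None) -> float:
    """Attribute level at which the function takes value ``v``.

    Only defined for continuous monotone functions; for unimodal input the
    limb must be named (index 0 or 1) because the inverse is ambiguous.
    Satisfies ``evaluate(vf, invert(vf, v)) == v`` to 1e-9.
    """
    if vf.kind != "continuous":
        raise ValueFunctionError("invert is defined for continuous functions")
    if not 0 <= v <= 1:
        raise ValueFunctionError("value must lie in [0, 1]")
    if len(vf.limbs) > 1 and limb is None:
        raise ValueFunctionError(
            f"{vf.attribute}: unimodal inverse is ambiguous; name a limb"
        )
    return vf.limbs[limb or 0].invert(v)


def construct_from_bisection(
    attribute: str,
    x_worst: float,
    x_best: float,
    mid_levels: Mapping[float, float] | None = None,
    source: str = "expert",
) -> ValueFunction:
    """Build a monotone value function from bisection-method answers.

    ``mid_levels`` maps elicited values (0.5 first, then 0.25/0.75,
    optionally 0.1/0.9) to the attribute levels judged to carry them.  The
    endpoints contribute (x_worst, 0) and (x_best, 1).  Levels must fall
    strictly between the endpoints and be ordered consistently with the
    orientation implied by worst < best or worst > best; inconsistent
    bisection answers raise.
    """
    if x_worst == x_best:
        raise ValueFunctionError("degenerate range: worst equals best level")
    pairs = [(x_worst, 0.0), (x_best, 1.0)]
    for value, level in (mid_levels or {}).items():
        if not 0 < value < 1:
            raise ValueFunctionError(f"elicited value {value} outside (0, 1)")
        lo, hi = min(x_worst, x_best), max(x_worst, x_best)
        if not lo < level < hi:
            raise ValueFunctionError(
                f"inconsistent bisection answer: level {level} for value {value} "
                f"outside ({lo}, {hi})"
            )
        pairs.append((float(level), float(value)))
    pairs.sort(key=lambda p: p[1])  # ascending in value
    x = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    dx = np.diff(x)
    if not (np.all(dx > 0) or np.all(dx < 0)):
        raise ValueFunctionError(
            "inconsistent bisection answers: levels not monotone in value"
        )
    return ValueFunction(attribute=attribute, source=source, limbs=[Limb(x, v)])


_RANGE_RE = re.compile(r"^\s*([0-9.,eE+-]+)\s*[–-]\s*([0-9.,eE+-]+)\s*$")


def _num(token: str) -> float:
    return float(token.replace(",", ""))


def parse_range(text: str) -> dict:
    """Parse a printed worst--best range into its numeric pieces.

    Handles plain monotone ranges (``0–3000``, ``24–10``), two-limb unimodal
    ranges (``0–7 // 14–7``), and binary levels (``0 or 1``).  Returns a dict
    with keys worst/best and, for two-limb ranges, worst2/peak2 (flagging
    ranges whose limbs do not share the peak level).
    """
    text = text.strip()
    if "//" in text:
        first, second = (part.strip() for part in text.split("//"))
        m1, m2 = _RANGE_RE.match(first), _RANGE_RE.match(second)
        if not (m1 and m2):
            raise ValueFunctionError(f"unparseable two-limb range: {text!r}")
        w1, b1 = _num(m1.group(1)), _num(m1.group(2))
        w2, b2 = _num(m2.group(1)), _num(m2.group(2))
        return {
            "worst": w1,
            "best": b1,
            "peak": b1,
            "worst2": w2,
            "peak2": b2,
            "flagged": b1 != b2,
        }
    if " or " in text:
        levels = sorted(_num(t) for t in text.split(" or "))
        return {"worst": levels[0], "best": levels[-1], "discrete": True,
                "levels": tuple(levels)}
    m = _RANGE_RE.match(text)
    if not m:
        raise ValueFunctionError(f"unparseable range: {text!r}")
    return {"worst": _num(m.group(1)), "best": _num(m.group(2))}


def build_unimodal(
    attribute: str,
    range_spec: str | None = None,
    *,
    worst: float | None = None,
    best: float | None = None,
    worst2: float | None = None,
    peak2: float | None = None,
    source: str = "expert",
) -> ValueFunction:
    """Two-limb value function from an ``a–b // c–b`` style range.

    Value 1 at the shared peak ``b``, value 0 at ``a`` and at ``c``, each
    limb linear unless mid points are supplied later.  Limbs with unequal
    peak levels (a few printed ranges have them) are accepted but flagged:
    each limb then peaks at its own best end and levels between the two
    limbs are outside the declared range.
    """
    if range_spec is not None:
        parsed = parse_range(range_spec)
        if "worst2" not in parsed:
            raise ValueFunctionError(f"{range_spec!r} is not a two-limb range")
        worst, best = parsed["worst"], parsed["best"]
        worst2, peak2 = parsed["worst2"], parsed["peak2"]
    if None in (worst, best, worst2):
        raise ValueFunctionError("unimodal construction needs both limbs")
    peak2 = best if peak2 is None else peak2
    limb1 = Limb(np.array([worst, best]), np.array([0.0, 1.0]))
    limb2 = Limb(np.array([worst2, peak2]), np.array([0.0, 1.0]))
    return ValueFunction(
        attribute=attribute,
        source=source,
        limbs=[limb1, limb2],
        flagged=(best != peak2),
    )


def classify_shape(vf: ValueFunction, tol: float = 0.02) -> str:
    """Classify a continuous value function as ``linear`` or ``nonlinear``.

    Linear iff, on every limb, no interior anchor deviates vertically from
    the chord between the limb endpoints by more than ``tol`` (on the value
    scale).  Invariant to affine rescaling of the attribute axis.  Discrete
    functions cannot be classified and raise.
    """
    if vf.kind != "continuous":
        raise ValueFunctionError("shape classification applies to continuous functions")
    for limb in vf.limbs:
        x0, x1 = limb.x[0], limb.x[-1]
        v0, v1 = limb.v[0], limb.v[-1]
        chord = v0 + (limb.x - x0) * (v1 - v0) / (x1 - x0)
        if np.max(np.abs(limb.v - chord)) > tol:
            return "nonlinear"
    return "linear"


@dataclass(frozen=True)
class QualityClassScheme:
    """Equal-width banding of [0, 1] into n ordered quality classes.

    Mirrors class-based assessment protocols (e.g. five classes bad /
    unsatisfactory / moderate / good / very good); class 1 is the best class
    when ``best_first`` (the default), matching best-to-worst listings.
    """

    n_classes: int = 5
    best_first: bool = True

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueFunctionError("a class scheme needs at least 2 classes")


def from_class_scheme(class_index: int, scheme: QualityClassScheme) -> float:
    """Midpoint value of a quality class's band on the [0, 1] value scale.

    Translates class-valued protocol outputs to the common scale: the best
    class maps into the top band (e.g. best of 5 -> 0.9, worst of 5 -> 0.1).
    """
    n = scheme.n_classes
    if not 1 <= class_index <= n:
        raise ValueFunctionError(f"class index {class_index} outside 1..{n}")
    rank_from_best = class_index - 1 if scheme.best_first else n - class_index
    width = 1.0 / n
    top = 1.0 - rank_from_best * width
    return top - width / 2


def linearize(vf: ValueFunction) -> ValueFunction:
    """Replace each limb by the straight chord between its endpoints.

    The 'assume linear value functions' simplification; discrete functions
    are returned unchanged.
    """
    if vf.kind == "discrete":
        return vf
    limbs = [
        Limb(np.array([l.x[0], l.x[-1]]), np.array([l.v[0], l.v[-1]]))
        for l in vf.limbs
    ]
    return ValueFunction(vf.attribute, vf.source, limbs, None, "continuous", vf.flagged)


def from_attribute(attr, mid_levels: Mapping[float, float] | None = None) -> ValueFunction:
    """Default value function implied by an attribute's printed range.

    Monotone ranges give the straight line from (worst, 0) to (best, 1)
    (through any supplied mid levels); two-limb ranges give the unimodal
    default; discrete attributes map their admissible levels linearly in
    listed order (worst level -> 0, best level -> 1).
    """
    if attr.discrete:
        levels = attr.levels or (attr.worst, attr.best)
        lv = list(levels)
        # honour printed direction: worst may be the numerically larger class
        if attr.worst is not None and attr.best is not None and attr.worst > attr.best:
            lv = sorted(lv, reverse=True)
        else:
            lv = sorted(lv)
        n = len(lv)
        table = {float(x): (i / (n - 1) if n > 1 else 1.0) for i, x in enumerate(lv)}
        return ValueFunction(attr.abbreviation, attr.source, [], table, "discrete")
    if attr.is_unimodal:
        return build_unimodal(
            attr.abbreviation,
            worst=attr.worst,
            best=attr.peak if attr.peak is not None else attr.best,
            worst2=attr.worst2,
            peak2=attr.peak2,
            source=attr.source,
        )
    return construct_from_bisection(
        attr.abbreviation, attr.worst, attr.best, mid_levels, source=attr.source
    )
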