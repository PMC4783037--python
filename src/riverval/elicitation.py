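"""Weight elicitation arithmetic and group consolidation diagnostics.

Weights are local scaling constants within one sibling group of the
objectives hierarchy.  Three elicitation procedures are supported: swing
(all objectives at worst, swing each to best, score 0–100 with the top
swing at 100), reversed swing (start from best, swing to worst; identical
scoring arithmetic, the difference is framing), and direct rating.  Scores
normalize to weights proportionally.  When several experts weight the same
objective, the group value is the median over contributing experts —
explicit 0 weights contribute, "not elicited / not applicable" entries (the
table symbol Ø) do not.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: sentinel for "no entry" (the Ø symbol in printed weight tables)
NOT_APPLICABLE = None


class ElicitationError(ValueError):
    pass


@dataclass
class SwingResponse:
    """One expert's swing scoring of a sibling group.

    ``objectives`` in swing-rank order with ``scores`` 0–100; the
    best-ranked swing scores exactly 100 and scores weakly decrease in rank.
    ``reversed_frame`` records a reversed-swing elicitation (best-to-worst
    framing); the weight arithmetic is unchanged.
    """

    objectives: tuple[str, ...]
    scores: tuple[float, ...]
    expert: str = ""
    reversed_frame: bool = False

    def __post_init__(self):
        self.objectives = tuple(self.objectives)
        self.scores = tuple(float(s) for s in self.scores)
        if len(self.objectives) != len(self.scores):
            raise ElicitationError("objectives and scores differ in length")
        if not self.scores:
            raise ElicitationError("empty swing response")
        if any(s < 0 for s in self.scores):
            raise ElicitationError("swing scores must be non-negative")
        if abs(self.scores[0] - 100) > 1e-9:
            raise ElicitationError(
                f"best-ranked swing must score 100, got {self.scores[0]}"
            )
        if any(a < b - 1e-9 for a, b in zip(self.scores, self.scores[1:])):
            raise ElicitationError("swing scores must weakly decrease in rank")


def _normalize(scores: Sequence[float]) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ElicitationError("no scores to normalize")
    if np.any(s < 0):
        raise ElicitationError("scores must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ElicitationError("all-zero scores cannot be normalized")
    return s / total


def swing_weights(response: SwingResponse) -> dict[str, float]:
    """Weights proportional to swing scores, summing to one."""
    w = _normalize(response.scores)
    return dict(zip(response.objectives, w.tolist()))


def reversed_swing_weights(response: SwingResponse) -> dict[str, float]:
    """Reversed-swing weights: scores express the value loss of swinging an
    objective from best to worst; the normalization is identical to swing."""
    return swing_weights(response)


def direct_rating_weights(ratings: Sequence[float]) -> np.ndarray:
    """Directly rated importances normalized to sum to one."""
    return _normalize(ratings)


def group_median(entries: Iterable[float | None]) -> float:
    """Median over contributing experts.

    ``None`` marks an entry that was not elicited or not applicable (Ø) and
    does not contribute; an explicit 0 does.  Even counts take the midpoint
    of the two central values.  Raises when nothing contributes.
    """
    contributing = [float(e) for e in entries if e is not None]
    if not contributing:
        raise ElicitationError("no contributing entries (all Ø)")
    return float(statistics.median(contributing))


def variation_stats(entries: Iterable[float | None], large_threshold: float = 0.4) -> dict:
    """Between-expert spread for one objective: range = max − min.

    The spread is "large" when the range reaches ``large_threshold``
    (inclusive).  Needs at least two contributing entries.
    """
    contributing = [float(e) for e in entries if e is not None]
    if len(contributing) < 2:
        raise ElicitationError("variation needs >= 2 contributing entries")
    rng = max(contributing) - min(contributing)
    return {"range": rng, "large": rng >= large_threshold,
            "n": len(contributing)}


@dataclass
class ExpertWeightTable:
    """Weights of several objectives from several experts (one table row per
    objective, one column per expert; ``None`` cells are Ø)."""

    objectives: tuple[str, ...]
    experts: tuple[str, ...]
    cells: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def column(self, expert: str) -> dict[str, float | None]:
        return {o: self.cells.get((o, expert)) for o in self.objectives}

    def row(self, objective: str) -> list[float | None]:
        return [self.cells.get((objective, e)) for e in self.experts]

    def medians(self) -> dict[str, float]:
        return {o: group_median(self.row(o)) for o in self.objectives
                if any(c is not None for c in self.row(o))}

    def validate_columns(self, tol: float = 0.015) -> list[str]:
        """Check that each expert's defined weights sum to ~1.

        The tolerance absorbs printed rounding (some published columns sum
        to 1.01); larger deviations are reported as violations.
        """
        problems = []
        for e in self.experts:
            vals = [c for c in self.column(e).values() if c is not None]
            if vals and abs(sum(vals) - 1.0) > tol:
                problems.append(f"{e}: weights sum to {sum(vals):.3f}, not 1")
        return problems


def global_weights(local: Mapping[str, Mapping[str, float]], hierarchy) -> dict[str, float]:
    """Diagnostic product-down-the-path weight of every node.

    ``local`` maps parent id -> {child id: local weight}.  Weighting is
    hierarchical (local to sibling groups); the global weight of a node is
    the product of local weights along its ancestor path and is reported for
    diagnostics such as keeping the top-n leaves.
    """
    out: dict[str, float] = {hierarchy.root.id: 1.0}
    stack = [hierarchy.root.id]
    while stack:
        nid = stack.pop()
        node = hierarchy.nodes[nid]
        if not node.children:
            continue
        ws = local.get(nid)
        if ws is None:
            ws = {c: 1 / len(node.children) for c in node.children}
        for cid in node.children:
            out[cid] = out[nid] * ws.get(cid, 0.0)
            stack.append(cid)
    return out


def bisection_consistency(
    responses: Sequence[tuple[float, float]], orientation: str = "increasing"
) -> list[str]:
    """Monotonicity check of bisection answers; empty list means pass.

    ``responses`` are (value, level) pairs in any order.  For an increasing
    attribute the elicited levels must increase with value (decrease for a
    decreasing attribute); every violated neighbouring pair is reported,
    naming both points.
    """
    if len(responses) < 3:
        raise ElicitationError("consistency check needs >= 3 responses")
    if orientation not in ("increasing", "decreasing"):
        raise ElicitationError(f"orientation {orientation!r} must be monotone")
    ordered = sorted((float(v), float(x)) for v, x in responses)
    violations = []
    sign = 1.0 if orientation == "increasing" else -1.0
    for (v1, x1), (v2, x2) in zip(ordered, ordered[1:]):
        if sign * (x2 - x1) < 0:
            violations.append(
                f"levels for values {v1:g} and {v2:g} are out of order "
                f"({x1:g} vs {x2:g} for an {orientation} attribute)"
            )
    return violations
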