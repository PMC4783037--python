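"""Seeded generators for hierarchies, preferences, states, and transcripts.

Everything the assessment engine consumes can be generated synthetically
with the statistical structure the analyses assume: a five-level
objectives hierarchy with prescribed per-level node counts, attributes
with increasing / decreasing / unimodal ranges, expert preference sets in
which a target fraction of value functions is non-linear and a target
fraction of aggregation choices is multiplicative, synergy factors drawn
from the four assessed levels, certainty equivalents that are risk averse
or risk prone but never neutral, and river-state tables with controlled
missingness.  One explicit seeded generator is threaded through every
draw, so identical spec + seed reproduce identical artifacts byte for
byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationSpec, SYNERGY_LEVELS
from .hierarchy import Attribute, Hierarchy, ObjectiveNode, ROOT_ID
from .risk_utility import CEPoints
from .simplification import PreferenceFixture
from .value_functions import ValueFunction, construct_from_bisection, invert

#: displacement (value scale) separating generated non-linear mid points
#: from the chord; safely above the 0.02 classification tolerance
NONLINEAR_DISPLACEMENT = (0.1, 0.35)

DEFAULT_LEVEL_COUNTS = (3, 7, 18, 51, 23)


@dataclass(frozen=True)
class GeneratorSpec:
    """Targets for one synthetic study.

    Defaults mirror the published study conditions: 3/7/18/51/23 objectives
    on levels 1–5, six experts, 81% non-linear value functions, 76%
    multiplicative aggregation choices, synergy factors uniform over
    {0.25, 0.5, 0.75, 1}, and a mixed risk pattern (averse at poor and
    good states, prone at the medium state).
    """

    level_counts: tuple[int, ...] = DEFAULT_LEVEL_COUNTS
    n_experts: int = 6
    pct_nonlinear: float = 0.81
    pct_multiplicative: float = 0.76
    synergy_distribution: tuple[tuple[float, float], ...] = (
        (0.25, 0.25), (0.5, 0.25), (0.75, 0.25), (1.0, 0.25)
    )
    risk_profile: str = "mixed"
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.level_counts or any(c < 1 for c in self.level_counts):
            raise ValueError("level counts must be positive")
        for p in (self.pct_nonlinear, self.pct_multiplicative, self.missingness):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        ks = [k for k, _ in self.synergy_distribution]
        if any(k not in SYNERGY_LEVELS for k in ks):
            raise ValueError(f"synergy levels must be among {SYNERGY_LEVELS}")
        if abs(sum(p for _, p in self.synergy_distribution) - 1.0) > 1e-9:
            raise ValueError("synergy distribution must sum to 1")
        if self.risk_profile not in ("averse", "prone", "mixed"):
            raise ValueError(f"unknown risk profile {self.risk_profile!r}")


def _experts(spec: GeneratorSpec) -> list[str]:
    return [f"E{i + 1}" for i in range(spec.n_experts)]


def generate_hierarchy(spec: GeneratorSpec) -> Hierarchy:
    """Random hierarchy with exactly the per-level node counts of ``spec``.

    Each node on level l+1 is attached to a uniformly drawn parent on
    level l.  Nodes that end up childless become lowest-level objectives
    and receive one or two attributes with randomized ranges (orientation
    drawn among increasing, decreasing, and unimodal).  Every node carries
    essentiality labels with at least one ``essential`` vote, so
    consolidating the generated hierarchy reproduces it.
    """
    rng = np.random.default_rng(spec.seed)
    experts = _experts(spec)
    nodes = [ObjectiveNode(ROOT_ID, "Ecological state", 0)]
    previous = [ROOT_ID]
    for level, count in enumerate(spec.level_counts, start=1):
        current = []
        # guarantee feasibility: the first len(previous) nodes spread over
        # all parents only when the level is at least as wide as the one
        # above; extra nodes draw parents uniformly
        parents = list(rng.choice(len(previous), size=count))
        for i in range(count):
            nid = f"L{level}N{i + 1}"
            labelled = rng.choice(len(experts),
                                  size=rng.integers(1, 3), replace=False)
            labels = {}
            for j, e in enumerate(labelled):
                labels[experts[int(e)]] = ("essential" if j == 0 else
                                           str(rng.choice(["essential",
                                                           "very_valuable",
                                                           "desirable"])))
            nodes.append(
                ObjectiveNode(nid, f"Objective {nid}", level,
                              parent=previous[int(parents[i])], labels=labels)
            )
            current.append(nid)
        previous = current
    catalogue: list[Attribute] = []
    by_id = {n.id: n for n in nodes}
    has_children = {n.parent for n in nodes if n.parent is not None}
    for node in nodes:
        if node.id in has_children or node.parent is None and len(nodes) > 1:
            continue
        for j in range(int(rng.integers(1, 3))):
            abbr = f"a_{node.id}_{j}"
            orientation = str(rng.choice(["increasing", "decreasing", "unimodal"]))
            lo = float(np.round(rng.uniform(0, 50), 3))
            span = float(np.round(rng.uniform(10, 100), 3))
            if orientation == "increasing":
                attr = Attribute(abbr, worst=lo, best=lo + span)
            elif orientation == "decreasing":
                attr = Attribute(abbr, worst=lo + span, best=lo)
            else:
                peak = float(np.round(lo + span * rng.uniform(0.3, 0.7), 3))
                attr = Attribute(abbr, worst=lo, best=peak, peak=peak,
                                 worst2=lo + span, peak2=peak)
            catalogue.append(attr)
            node.attributes.append(abbr)
    return Hierarchy(nodes, catalogue)


def _monotone_vf(
    attr: Attribute, nonlinear: bool, rng: np.random.Generator, source: str
) -> tuple[ValueFunction, str]:
    w, b = attr.worst, attr.best
    if nonlinear:
        d = float(rng.uniform(*NONLINEAR_DISPLACEMENT))
        s = 1.0 if rng.random() < 0.5 else -1.0
        fracs = {0.25: 0.25 + s * d / 2, 0.5: 0.5 + s * d, 0.75: 0.75 + s * d / 2}
    else:
        fracs = {0.25: 0.25, 0.5: 0.5, 0.75: 0.75}
    mids = {v: w + (b - w) * f for v, f in fracs.items()}
    vf = construct_from_bisection(attr.abbreviation, w, b, mids, source=source)
    return vf, ("nonlinear" if nonlinear else "linear")


def _unimodal_vf(
    attr: Attribute, nonlinear: bool, rng: np.random.Generator, source: str
) -> tuple[ValueFunction, str]:
    from .value_functions import Limb

    limbs = []
    for w, b in ((attr.worst, attr.peak), (attr.worst2, attr.peak2)):
        if nonlinear:
            d = float(rng.uniform(*NONLINEAR_DISPLACEMENT))
            s = 1.0 if rng.random() < 0.5 else -1.0
            fracs = [0.25 + s * d / 2, 0.5 + s * d, 0.75 + s * d / 2]
        else:
            fracs = [0.25, 0.5, 0.75]
        xs = [w] + [w + (b - w) * f for f in fracs] + [b]
        vs = [0.0, 0.25, 0.5, 0.75, 1.0]
        if xs[0] > xs[-1]:
            xs, vs = xs[::-1], vs[::-1]
        limbs.append(Limb(np.array(xs), np.array(vs)))
    vf = ValueFunction(attr.abbreviation, source, limbs)
    return vf, ("nonlinear" if nonlinear else "linear")


def generate_ce(spec: GeneratorSpec, rng: np.random.Generator,
                expert: str = "") -> CEPoints:
    """CE triple following the spec's risk profile (never neutral)."""
    def offset() -> float:
        return float(rng.uniform(0.05, 0.1))

    if spec.risk_profile == "averse":
        pts = (0.25 - offset(), 0.5 - offset(), 0.75 - offset())
    elif spec.risk_profile == "prone":
        pts = (0.25 + offset(), 0.5 + offset(), 0.75 + offset())
    else:  # averse at poor and good states, prone at the medium state
        pts = (0.25 - offset(), 0.5 + offset(), 0.75 - offset())
    return CEPoints(*pts, expert=expert)


@dataclass
class GeneratedPreferences:
    """A synthetic preference set plus its generating ground truth."""

    fixture: PreferenceFixture
    shape_truth: dict[str, str] = field(default_factory=dict)
    method_truth: dict[str, str] = field(default_factory=dict)
    synergy_truth: dict[str, float] = field(default_factory=dict)
    ce_sets: dict[str, CEPoints] = field(default_factory=dict)


def generate_preferences(
    spec: GeneratorSpec, h: Hierarchy | None = None
) -> GeneratedPreferences:
    """Synthetic expert preferences for a hierarchy.

    Value functions are non-linear with probability ``pct_nonlinear``
    (mid-value point displaced at least 0.1 from the chord, so generated
    labels are unambiguous for the shape classifier); aggregation methods
    multiplicative with probability ``pct_multiplicative`` with synergy
    drawn from the spec distribution; weights are flat-simplex (Dirichlet)
    draws; one CE set per expert follows the risk profile.
    """
    if h is None:
        h = generate_hierarchy(spec)
    rng = np.random.default_rng(spec.seed + 1)
    value_functions: dict[str, list[ValueFunction]] = {}
    shape_truth: dict[str, str] = {}
    for abbr, attr in h.catalogue.items():
        if not attr.has_value_function:
            continue
        nonlinear = bool(rng.random() < spec.pct_nonlinear)
        if attr.discrete:
            n = len(attr.levels or (attr.worst, attr.best))
            table = {float(x): i / max(n - 1, 1)
                     for i, x in enumerate(attr.levels or (attr.worst, attr.best))}
            value_functions[abbr] = [
                ValueFunction(abbr, attr.source, [], table, "discrete")
            ]
            continue
        make = _unimodal_vf if attr.is_unimodal else _monotone_vf
        vf, label = make(attr, nonlinear, rng, attr.source)
        value_functions[abbr] = [vf]
        shape_truth[abbr] = label
    specs: dict[str, AggregationSpec] = {}
    method_truth: dict[str, str] = {}
    synergy_truth: dict[str, float] = {}
    ks = np.array([k for k, _ in spec.synergy_distribution])
    ps = np.array([p for _, p in spec.synergy_distribution])
    for node in h.nodes.values():
        if node.is_leaf:
            continue
        weights = tuple(np.round(rng.dirichlet(np.ones(len(node.children))), 12))
        multiplicative = bool(rng.random() < spec.pct_multiplicative)
        if multiplicative:
            k = float(rng.choice(ks, p=ps))
            specs[node.id] = AggregationSpec(node.id, "multiplicative",
                                             weights, k=k)
            synergy_truth[node.id] = k
            method_truth[node.id] = "multiplicative"
        else:
            specs[node.id] = AggregationSpec(node.id, "additive", weights)
            method_truth[node.id] = "additive"
    ce_sets = {e: generate_ce(spec, rng, e) for e in _experts(spec)}
    fixture = PreferenceFixture(h, value_functions, specs)
    return GeneratedPreferences(fixture, shape_truth, method_truth,
                                synergy_truth, ce_sets)


def generate_states(
    h: Hierarchy,
    n: int,
    missingness: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """River-state table: one row per state, one column per attribute.

    Measurements are uniform within each attribute's admissible range
    (over both limbs for unimodal attributes); a fraction ``missingness``
    of cells is NaN.  Attributes without a value function are left
    unmeasured.  All states remain evaluable by the roll-up as long as the
    missingness leaves at least one assessable leaf.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cols = [a for a, attr in h.catalogue.items() if attr.has_value_function]
    data = {}
    for abbr in cols:
        attr = h.catalogue[abbr]
        if attr.discrete:
            levels = np.array(attr.levels or (attr.worst, attr.best), dtype=float)
            draws = rng.choice(levels, size=n)
        else:
            limbs = attr.domain()
            lo = min(l[0] for l in limbs)
            hi = max(l[1] for l in limbs)
            draws = rng.uniform(lo, hi, size=n)
            if len(limbs) == 2 and limbs[0][1] < limbs[1][0]:
                # a gap between flagged limbs: fold draws into the limbs
                gap_lo, gap_hi = limbs[0][1], limbs[1][0]
                in_gap = (draws > gap_lo) & (draws < gap_hi)
                draws[in_gap] = gap_lo
        if missingness > 0:
            mask = rng.random(n) < missingness
            draws = np.where(mask, np.nan, draws)
        data[abbr] = draws
    return pd.DataFrame(data, columns=cols)


def generate_bisection_responses(
    true_vf: ValueFunction,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    values: Sequence[float] = (0.25, 0.5, 0.75),
) -> list[tuple[float, float]]:
    """Simulated bisection transcript for a monotone value function.

    For each elicited value the answered level is the true inverse plus
    Gaussian noise on the attribute scale, clipped to the range and
    re-monotonized (answers are sorted into the order a consistent expert
    would give).  With ``noise_sd=0`` the transcript reconstructs the
    generating function exactly at all elicited values.
    """
    if not true_vf.monotone:
        raise ValueError("bisection transcripts need a monotone function")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    limb = true_vf.limbs[0]
    lo, hi = limb.lo, limb.hi
    vals = sorted(float(v) for v in values)
    true_levels = np.array([invert(true_vf, v) for v in vals])
    levels = true_levels.copy()
    if noise_sd > 0:
        span = hi - lo
        margin = 1e-6 * span
        levels = np.clip(levels + rng.normal(0.0, noise_sd, size=levels.size),
                         lo + margin, hi - margin)
        # re-monotonize strictly, in the direction a consistent expert
        # answers: levels increase with value for increasing functions,
        # decrease for decreasing ones
        levels = np.sort(levels)
        for i in range(1, levels.size):
            if levels[i] <= levels[i - 1]:
                levels[i] = levels[i - 1] + 1e-9 * span
        levels = np.minimum(levels, hi - 1e-7 * span)
        for i in range(levels.size - 2, -1, -1):
            if levels[i] >= levels[i + 1]:
                levels[i] = levels[i + 1] - 1e-9 * span
    ascending = true_levels[0] <= true_levels[-1]
    levels = np.sort(levels)
    if not ascending:
        levels = levels[::-1]
    return list(zip(vals, levels.tolist()))
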