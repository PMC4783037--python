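"""Packaged preference and hierarchy fixtures.

The package ships a structured-text transcription of the published expert
elicitation for a Swiss gravel-bed river (the lower Wigger):

* ``attributes.csv`` — the attribute catalogue: 80 printed rows covering 69
  distinct attribute numbers (number 24 was never assigned; the printed
  numbering is preserved verbatim), with measures, units, worst–best
  ranges, and source tags (expert abbreviation or ``literature``).
* ``hierarchy_consolidated_synthetic.json`` — the consolidated objectives
  hierarchy.  The published tree is only available as a figure, so this
  file is a synthetic transcription: level counts (3/7/18/51/23 objectives
  on levels 1–5), branch names, and all objectives named in the running
  text are as published; the interior wiring and leaf-attribute placement
  are reconstructed.
* ``level1_weights.csv`` — level-1 weights, aggregation choices, and
  synergy factors of the five contributing experts (``Ø`` = not elicited).
* ``aggregation_choices.csv`` — the 49 per-branch aggregation decisions
  (37 multiplicative, 12 additive).  Branch totals and every named decision
  are as published; the remaining per-record expert attributions are
  placeholders consistent with the published counts.
"""

from __future__ import annotations

import csv
import json
from importlib import resources

import numpy as np
import pandas as pd

from .elicitation import ExpertWeightTable
from .hierarchy import Attribute, Hierarchy
from .risk_utility import CEPoints
from .value_functions import (
    Limb,
    ValueFunction,
    construct_from_bisection,
    from_attribute,
    parse_range,
)

LEVEL1_EXPERTS = ("Fish", "BioA", "BioB", "BioPhys", "Phys")


def _data(name: str):
    return resources.files("riverval.data").joinpath(name)


def load_attribute_table() -> pd.DataFrame:
    """The attribute catalogue as a DataFrame with verbatim printed ranges."""
    with resources.as_file(_data("attributes.csv")) as path:
        return pd.read_csv(path, dtype={"number": int, "discrete": int})


def load_attribute_catalogue() -> dict[str, Attribute]:
    """Attribute catalogue keyed by abbreviation, with parsed ranges.

    Abbreviations are unique (numbers repeat when several experts assessed
    the same quantity).  Rows whose printed range is ``No value function``
    yield attributes with ``has_value_function=False``; two-limb ranges
    whose limbs do not share the peak level are flagged for review.
    """
    out: dict[str, Attribute] = {}
    for row in load_attribute_table().itertuples(index=False):
        kwargs = dict(
            abbreviation=row.abbreviation,
            number=int(row.number),
            measure=row.measure,
            unit=row.unit,
            discrete=bool(row.discrete),
            source=row.source,
        )
        if row.range.strip() == "No value function":
            kwargs.update(worst=None, best=None, has_value_function=False,
                          note="no value function available")
        else:
            parsed = parse_range(row.range)
            kwargs.update(
                worst=parsed["worst"],
                best=parsed["best"],
                peak=parsed.get("peak"),
                worst2=parsed.get("worst2"),
                peak2=parsed.get("peak2"),
                flagged=parsed.get("flagged", False),
            )
            if kwargs["flagged"]:
                kwargs["note"] = "limb peaks differ; stored as printed"
            if bool(row.discrete):
                levels = parsed.get("levels")
                if levels is None:
                    lo = int(min(parsed["worst"], parsed["best"]))
                    hi = int(max(parsed["worst"], parsed["best"]))
                    levels = tuple(float(x) for x in range(lo, hi + 1))
                kwargs["levels"] = levels
                kwargs["discrete"] = True
        attr = Attribute(**kwargs)
        if attr.abbreviation in out:
            raise ValueError(f"duplicate abbreviation {attr.abbreviation}")
        out[attr.abbreviation] = attr
    return out


def load_consolidated_hierarchy() -> Hierarchy:
    """The consolidated objectives hierarchy (synthetic transcription).

    102 objectives on levels 1–5 (3/7/18/51/23) below the "ecological
    state" root, with the full attribute catalogue attached to the leaves.
    The "good water quality" objective is included as a structural
    placeholder flagged non-assessable (it was excluded from attribute
    elicitation).
    """
    doc = json.loads(_data("hierarchy_consolidated_synthetic.json").read_text("utf-8"))
    return Hierarchy.from_dict(doc)


def load_value_function_records() -> list[ValueFunction]:
    """Default value-function records implied by the attribute catalogue.

    One record per catalogue row that carries a range: monotone ranges give
    the chord through (worst, 0)–(best, 1), two-limb ranges the unimodal
    default, discrete rows the enumerated mapping.  The single row without
    a value function (``sussolidlow``) contributes a continuous record with
    no curve, so census totals match the published arithmetic.
    """
    records = []
    for attr in load_attribute_catalogue().values():
        if not attr.has_value_function:
            records.append(
                ValueFunction(attribute=attr.abbreviation, source=attr.source,
                              limbs=[], table=None, kind="continuous",
                              flagged=True)
            )
            continue
        records.append(from_attribute(attr))
    return records


def load_level1_table() -> pd.DataFrame:
    """Verbatim level-1 weights / aggregation / synergy table."""
    with resources.as_file(_data("level1_weights.csv")) as path:
        return pd.read_csv(path, index_col="row")


def load_level1_weight_table() -> ExpertWeightTable:
    """Level-1 weights of the five experts as an :class:`ExpertWeightTable`.

    Explicit 0 weights (one expert based the whole assessment on the
    biological branch, zero-weighting the other two) are kept as 0 — they
    contribute to group medians, unlike Ø cells.
    """
    df = load_level1_table()
    objectives = ("physical", "chemical", "biological")
    cells = {}
    for obj in objectives:
        for expert in LEVEL1_EXPERTS:
            raw = str(df.loc[obj, expert]).strip()
            cells[(obj, expert)] = None if raw == "Ø" else float(raw)
    return ExpertWeightTable(objectives, LEVEL1_EXPERTS, cells)


def load_level1_synergies() -> dict[str, float | None]:
    """Synergy factors chosen for aggregating the three level-1 objectives.

    ``None`` marks Ø entries (no aggregation required: the expert put full
    weight on one branch); these do not contribute to the group median.
    """
    df = load_level1_table()
    out = {}
    for expert in LEVEL1_EXPERTS:
        raw = str(df.loc["synergy", expert]).strip()
        out[expert] = None if raw == "Ø" else float(raw)
    return out


def load_level1_methods() -> dict[str, str | None]:
    """Aggregation method each expert chose at the top of the hierarchy."""
    df = load_level1_table()
    names = {"add": "additive", "mult": "multiplicative"}
    out = {}
    for expert in LEVEL1_EXPERTS:
        raw = str(df.loc["aggregation", expert]).strip()
        out[expert] = None if raw == "Ø" else names[raw]
    return out


def load_aggregation_choices() -> pd.DataFrame:
    """The 49 recorded aggregation decisions (branch, expert, node, method)."""
    with resources.as_file(_data("aggregation_choices.csv")) as path:
        return pd.read_csv(path)


def nase_value_function() -> ValueFunction:
    """Adult-nase value function: the published worked example.

    0 individuals is the worst-possible state, 2000 the best; 300
    individuals carry value 0.5 (the mid-value point) — the first few fish
    matter most, so the curve rises steeply before flattening.
    """
    return construct_from_bisection("adultn", 0.0, 2000.0, {0.5: 300.0},
                                    source="Fish")


def example_ce_sets() -> dict[str, CEPoints]:
    """Synthetic certainty-equivalent sets with the published qualitative
    pattern.

    The exact elicited CE values live in unavailable supplementary tables;
    these stand-ins reproduce the reported structure: every expert risk
    averse at root values 0.25 and 0.75, and the BioA-style set risk prone
    at 0.5 (utility 0.6 there, i.e. CE 0.6 for the 50-50 lottery).
    """
    return {
        "BioA": CEPoints(x25=0.18, x50=0.60, x75=0.68, expert="BioA"),
        "BioB": CEPoints(x25=0.18, x50=0.44, x75=0.68, expert="BioB"),
        "BioPhys": CEPoints(x25=0.20, x50=0.45, x75=0.70, expert="BioPhys"),
    }
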