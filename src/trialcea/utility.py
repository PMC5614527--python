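"""SF-6D utility scoring and area-under-the-curve QALYs.

Health-related quality of life is measured with the SF-12; response
permutations map onto the six-dimension SF-6D health-state classification
(physical functioning, role limitation, social functioning, pain, mental
health, vitality).  A standard-gamble-valued tariff converts each state to
a utility index (UK valuation spans 0.345 to 1 for full health).

The published tariff coefficients are deliberately NOT shipped with this
package: users supply them as a CSV (columns ``dimension, level,
decrement``; rows with dimension ``intercept`` and ``most_severe`` set the
constant and the extra decrement applied when any dimension is at its worst
level).  The test suite exercises the scoring machinery with a synthetic
toy tariff.

QALYs over the trial horizon are the area under the piecewise-linear
utility-time curve (trapezoid rule) through the assessments at 0, 6 and 12
months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SF6D_DIMENSIONS",
    "TariffTable",
    "SF12Mapping",
    "sf12_to_sf6d_state",
    "score_state",
    "qaly_auc",
]

SF6D_DIMENSIONS = (
    "physical_functioning",
    "role_limitation",
    "social_functioning",
    "pain",
    "mental_health",
    "vitality",
)


@dataclass(frozen=True)
class TariffTable:
    """Utility decrements per (dimension, level).

    ``decrements[(dim, level)]`` is the (non-positive) utility loss for
    being at ``level`` of ``dim``; level 1 always carries decrement 0.
    ``most_severe`` is an optional extra decrement applied once if any
    dimension sits at its worst level.  ``floor`` (if given) is the minimum
    attainable index and is only enforced when ``clamp_to_floor`` is set.
    """

    decrements: dict[tuple[str, int], float]
    intercept: float = 1.0
    most_severe: float = 0.0
    floor: float | None = None
    clamp_to_floor: bool = False
    levels: dict[str, int] = field(init=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        levels: dict[str, int] = {}
        for (dim, lvl), dec in self.decrements.items():
            if dec > 0:
                raise ValueError(f"decrement for ({dim}, {lvl}) is positive")
            if lvl == 1 and dec != 0:
                raise ValueError(f"level-1 decrement for {dim!r} must be 0")
            levels[dim] = max(levels.get(dim, 1), lvl)
        object.__setattr__(self, "levels", levels)

    @classmethod
    def from_csv(cls, source, clamp_to_floor: bool = False) -> "TariffTable":
        df = pd.read_csv(source)
        required = {"dimension", "level", "decrement"}
        if missing := required - set(df.columns):
            raise ValueError(f"tariff file missing column(s): {sorted(missing)}")
        intercept, most_severe, floor = 1.0, 0.0, None
        decrements: dict[tuple[str, int], float] = {}
        for row in df.itertuples(index=False):
            dim = str(row.dimension)
            if dim == "intercept":
                intercept = float(row.decrement)
            elif dim == "most_severe":
                most_severe = float(row.decrement)
            elif dim == "floor":
                floor = float(row.decrement)
            else:
                decrements[(dim, int(row.level))] = float(row.decrement)
        return cls(
            decrements=decrements,
            intercept=intercept,
            most_severe=most_severe,
            floor=floor,
            clamp_to_floor=clamp_to_floor,
        )

    def worst_state(self) -> dict[str, int]:
        return dict(self.levels)


def score_state(state: dict[str, int], tariff: TariffTable) -> float:
    """Utility index of an SF-6D state: intercept + sum of decrements
    (+ the most-severe term when some dimension is at its worst level)."""
    total = tariff.intercept
    any_worst = False
    for dim, lvl in state.items():
        if dim not in tariff.levels:
            raise KeyError(f"tariff has no dimension {dim!r}")
        if not 1 <= lvl <= tariff.levels[dim]:
            raise ValueError(
                f"level {lvl} out of range 1..{tariff.levels[dim]} for {dim!r}"
            )
        if lvl > 1:
            key = (dim, lvl)
            if key not in tariff.decrements:
                raise KeyError(f"tariff missing decrement for {key}")
            total += tariff.decrements[key]
        if lvl == tariff.levels[dim] and tariff.levels[dim] > 1:
            any_worst = True
    if any_worst:
        total += tariff.most_severe
    if tariff.clamp_to_floor and tariff.floor is not None:
        total = max(total, tariff.floor)
    return total


@dataclass(frozen=True)
class SF12Mapping:
    """Rule table mapping SF-12 responses onto SF-6D levels.

    Each rule assigns ``level`` of ``dimension`` when the defining item's
    response falls in ``responses``.  For a dimension, rules are evaluated
    from the highest level down; the first match wins and level 1 is the
    default.  Loaded from a CSV with columns ``dimension, level, item,
    responses`` (responses '|' separated, e.g. ``4|5``).
    """

    rules: dict[str, list[tuple[int, str, frozenset[int]]]]
    item_levels: dict[str, int]

    @classmethod
    def from_csv(cls, source, item_levels: dict[str, int] | None = None) -> "SF12Mapping":
        df = pd.read_csv(source)
        required = {"dimension", "level", "item", "responses"}
        if missing := required - set(df.columns):
            raise ValueError(f"mapping file missing column(s): {sorted(missing)}")
        rules: dict[str, list[tuple[int, str, frozenset[int]]]] = {}
        inferred: dict[str, int] = {}
        for row in df.itertuples(index=False):
            resp = frozenset(int(r) for r in str(row.responses).split("|"))
            rules.setdefault(str(row.dimension), []).append(
                (int(row.level), str(row.item), resp)
            )
            inferred[str(row.item)] = max(inferred.get(str(row.item), 1), max(resp))
        for dim in rules:
            rules[dim].sort(key=lambda t: -t[0])
        return cls(rules=rules, item_levels=item_levels or inferred)


def sf12_to_sf6d_state(response: dict[str, int], mapping: SF12Mapping) -> dict[str, int]:
    """Deterministically classify a complete SF-12 response into an SF-6D
    state.  Raises if any referenced item is absent or out of range."""
    for item, r in response.items():
        top = mapping.item_levels.get(item)
        if top is not None and not 1 <= r <= top:
            raise ValueError(f"item {item!r} response {r} outside range 1..{top}")
    state: dict[str, int] = {}
    for dim, rules in mapping.rules.items():
        level = 1
        for lvl, item, resp_set in rules:
            if item not in response:
                raise KeyError(f"response missing item {item!r} needed for {dim!r}")
            if response[item] in resp_set:
                level = lvl
                break
        state[dim] = level
    return state


def qaly_auc(
    utilities,
    times=(0.0, 0.5, 1.0),
    horizon: float = 1.0,
) -> float:
    """QALYs accrued to ``horizon`` (years) by the trapezoid rule.

    ``utilities`` are the index values at the assessment ``times`` (years,
    strictly increasing, starting at 0).  The horizon must coincide with an
    assessment time and every utility inside it must be observed — multiple
    imputation runs upstream of this step.
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times, dtype=float)
    if u.shape != t.shape:
        raise ValueError("utilities and times must have equal length")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("assessment times must start at 0 and strictly increase")
    if horizon > t[-1]:
        raise ValueError(f"horizon {horizon} lies beyond the last assessment {t[-1]}")
    inside = t <= horizon
    if not np.any(np.isclose(t, horizon)):
        raise ValueError(f"horizon {horizon} is not an assessment time")
    u_in, t_in = u[inside], t[inside]
    if np.any(np.isnan(u_in)):
        raise ValueError("missing utility inside the horizon; impute first")
    return float(np.trapezoid(u_in, t_in))
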