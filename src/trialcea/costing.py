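"""Per-participant costing under NHS/PSS and societal perspectives.

Resource-use counts collected by questionnaire are valued with a unit-cost
table (GBP, 2013/14 prices).  The NHS/PSS perspective covers primary- and
secondary-care contacts plus prescriptions; the societal perspective adds
productivity losses (human-capital approach for paid work, proxy-good
approach for unpaid housekeeping work), private complementary therapies,
out-of-pocket spending, and a value-added-tax adjustment of the NHS/PSS
component.  Intervention delivery costs enter as per-arm micro-costed
constants applied once, in the first six-month window.  Hospital admissions
are excluded from both perspectives (they were unrelated to the condition
of interest) and nothing is discounted over the 12-month horizon.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "UnitCostTable",
    "CostBreakdown",
    "load_unit_costs",
    "cost_nhs_pss",
    "productivity_cost",
    "cost_societal",
    "DEFAULT_INTERVENTION_COSTS",
]

# Default unit costs (GBP 2013/14).  National-source values for primary and
# community care, reference costs for imaging, formulary-based medication
# constants, ONS wage rates for productivity, and a mean market price for
# patient-reported private therapies.
_DEFAULT_UNIT_COST_CSV = """\
category,unit_cost,unit_description,perspective_membership
gp_consultation,66,Consultation with general practitioner (per 17 minute contact),nhs_pss
gp_phone_ooh,27,Out of hours telephone consultation with general practitioner (per 7.1 minute contact),nhs_pss
nurse_consultation,13,Consultation with practice nurse (per 15.5 minute contact),nhs_pss
nurse_phone_ooh,10,Out of hours telephone consultation with practice nurse (per 15.5 minute contact),nhs_pss
gynaecologist,134,Consultation with gynaecologist (per contact),nhs_pss
counsellor,112,Consultation with a counsellor or psychologist (per 50 minute contact),nhs_pss
physiotherapy,14,Physiotherapy (per 23.3 minute contact),nhs_pss
xray,91,X-ray (per scan),nhs_pss
prescription_6m,38,Prescription medicines (per 6 months),nhs_pss
hrt_repeat_3m,19,Repeat prescription for HRT (per 3 months),nhs_pss
repeat_prescription,8,Repeat prescription without seeing the doctor (per prescription),nhs_pss
full_time_day,93,Time off paid work (full-time employed; per day),societal_only
part_time_day,67,Time off paid work (part-time employed; per day),societal_only
unpaid_work_hour,8,Time off unpaid work (per hour of housekeeping work),societal_only
private_therapy,51,Private therapy (mean estimate of patient-reported therapies),societal_only
"""

#: Micro-costed development + delivery cost per woman, by arm, applied once
#: in the first 6-month window (delivery occurs during months 0-6).
DEFAULT_INTERVENTION_COSTS: dict[str, float] = {
    "control": 0.0,
    "social": 37.0,
    "dvd": 78.0,
}

#: NHS/PSS resource categories counted per follow-up period.
NHS_PSS_CATEGORIES = (
    "gp_consultation",
    "gp_phone_ooh",
    "nurse_consultation",
    "nurse_phone_ooh",
    "gynaecologist",
    "counsellor",
    "physiotherapy",
    "xray",
    "prescription_6m",
    "hrt_repeat_3m",
    "repeat_prescription",
)

_REQUIRED_COLUMNS = {"category", "unit_cost", "unit_description"}
_VALID_PERSPECTIVES = {"nhs_pss", "societal_only"}


@dataclass(frozen=True)
class UnitCostTable:
    """Resource category -> unit cost (GBP 2013/14), with perspective tags."""

    unit_costs: dict[str, float]
    descriptions: dict[str, str] = field(default_factory=dict)
    perspectives: dict[str, str] = field(default_factory=dict)
    vat_rate: float = 0.20
    intervention_costs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERVENTION_COSTS)
    )

    def __post_init__(self) -> None:
        for cat, c in self.unit_costs.items():
            if c < 0:
                raise ValueError(f"unit cost for {cat!r} is negative ({c})")
        if not 0 <= self.vat_rate < 1:
            raise ValueError(f"vat_rate must lie in [0, 1), got {self.vat_rate}")

    def lookup(self, category: str) -> float:
        try:
            return self.unit_costs[category]
        except KeyError:
            raise KeyError(
                f"resource category {category!r} not present in the unit-cost table"
            ) from None

    def nhs_pss_categories(self) -> list[str]:
        return [c for c, p in self.perspectives.items() if p == "nhs_pss"]

    def intervention_cost(self, arm: str) -> float:
        try:
            return self.intervention_costs[arm]
        except KeyError:
            raise KeyError(f"no intervention cost configured for arm {arm!r}") from None


@dataclass(frozen=True)
class CostBreakdown:
    """Per-woman cost decomposition for one follow-up period.

    ``nhs_pss_total`` and ``societal_total`` are exact sums (to the penny)
    of the components listed beneath them.
    """

    per_category: dict[str, float]
    intervention: float
    nhs_pss_total: float
    productivity_paid: float
    productivity_unpaid: float
    private_therapy: float
    out_of_pocket: float
    vat: float
    societal_total: float


def load_unit_costs(
    source: str | None = None,
    vat_rate: float = 0.20,
    intervention_costs: dict[str, float] | None = None,
) -> UnitCostTable:
    """Read a unit-cost CSV (columns: category, unit_cost, unit_description,
    optional perspective_membership); ``source=None`` loads the built-in
    2013/14 defaults."""
    if source is None:
        df = pd.read_csv(io.StringIO(_DEFAULT_UNIT_COST_CSV))
    else:
        df = pd.read_csv(source)
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"unit-cost table missing column(s): {sorted(missing)}")
    extra = set(df.columns) - _REQUIRED_COLUMNS - {"perspective_membership"}
    if extra:
        raise ValueError(f"unit-cost table has unknown column(s): {sorted(extra)}")
    if df["category"].duplicated().any():
        dupes = sorted(df.loc[df["category"].duplicated(), "category"])
        raise ValueError(f"duplicate categories in unit-cost table: {dupes}")
    if (df["unit_cost"] < 0).any():
        bad = sorted(df.loc[df["unit_cost"] < 0, "category"])
        raise ValueError(f"negative unit cost for: {bad}")
    if "perspective_membership" in df.columns:
        bad = set(df["perspective_membership"]) - _VALID_PERSPECTIVES
        if bad:
            raise ValueError(f"unknown perspective_membership value(s): {sorted(bad)}")
        persp = dict(zip(df["category"], df["perspective_membership"]))
    else:
        persp = {c: "nhs_pss" for c in df["category"]}
    return UnitCostTable(
        unit_costs=dict(zip(df["category"], df["unit_cost"].astype(float))),
        descriptions=dict(zip(df["category"], df["unit_description"])),
        perspectives=persp,
        vat_rate=vat_rate,
        intervention_costs=(
            dict(DEFAULT_INTERVENTION_COSTS)
            if intervention_costs is None
            else dict(intervention_costs)
        ),
    )


def _get(record, key, default=0.0):
    """Pull a numeric field from a dict-like or pandas row; NaN -> NaN."""
    try:
        v = record[key]
    except (KeyError, IndexError):
        return default
    return default if v is None else float(v)


def cost_nhs_pss(
    record,
    costs: UnitCostTable,
    include_intervention: bool = False,
) -> CostBreakdown:
    """Value a participant's NHS/PSS resource use for one period.

    ``record`` is any mapping (dict, pandas row) with count fields named by
    unit-cost category; absent categories count as zero.  With
    ``include_intervention`` the per-arm delivery constant (``record['arm']``)
    is added — used for the period in which the intervention is delivered.
    """
    per_category: dict[str, float] = {}
    total = 0.0
    for cat in costs.nhs_pss_categories():
        n = _get(record, cat)
        if n < 0:
            raise ValueError(f"negative count for category {cat!r}: {n}")
        c = round(n * costs.lookup(cat), 2)
        per_category[cat] = c
        total += c
    intervention = 0.0
    if include_intervention:
        intervention = costs.intervention_cost(record["arm"])
    total = round(total + intervention, 2)
    return CostBreakdown(
        per_category=per_category,
        intervention=intervention,
        nhs_pss_total=total,
        productivity_paid=0.0,
        productivity_unpaid=0.0,
        private_therapy=0.0,
        out_of_pocket=0.0,
        vat=0.0,
        societal_total=total,
    )


def productivity_cost(
    days_off_paid: float,
    employment: str,
    hours_off_unpaid: float,
    costs: UnitCostTable,
) -> tuple[float, float]:
    """(paid, unpaid) productivity losses in GBP.

    Paid work time is valued at the gross daily wage for the woman's
    employment pattern (human capital approach); time off unpaid work is
    valued at the market price of an hour of housekeeping work (proxy good
    approach).  Women not in paid employment incur no paid-work loss.
    """
    if days_off_paid < 0 or hours_off_unpaid < 0:
        raise ValueError("time off work cannot be negative")
    if employment == "full_time":
        paid = days_off_paid * costs.lookup("full_time_day")
    elif employment == "part_time":
        paid = days_off_paid * costs.lookup("part_time_day")
    elif employment == "not_employed":
        paid = 0.0
    else:
        raise ValueError(f"unknown employment category {employment!r}")
    unpaid = hours_off_unpaid * costs.lookup("unpaid_work_hour")
    return round(paid, 2), round(unpaid, 2)


def cost_societal(
    record,
    costs: UnitCostTable,
    vat_rate: float | None = None,
    include_intervention: bool = False,
) -> CostBreakdown:
    """Value a participant's resource use from the societal perspective.

    societal_total = (1 + VAT) x NHS/PSS component
                     + productivity (paid + unpaid) + private therapy
                     + out-of-pocket spending.
    """
    if vat_rate is None:
        vat_rate = costs.vat_rate
    if not 0 <= vat_rate < 1:
        raise ValueError(f"vat_rate must lie in [0, 1), got {vat_rate}")
    nhs = cost_nhs_pss(record, costs, include_intervention=include_intervention)
    vat = round(nhs.nhs_pss_total * vat_rate, 2)
    paid, unpaid = productivity_cost(
        _get(record, "days_off_paid"),
        record.get("employment", "not_employed")
        if hasattr(record, "get")
        else record["employment"],
        _get(record, "hours_off_unpaid"),
        costs,
    )
    private = round(_get(record, "private_therapy") * costs.lookup("private_therapy"), 2)
    if private < 0:
        raise ValueError("negative private-therapy contact count")
    oop = round(_get(record, "out_of_pocket"), 2)
    if oop < 0:
        raise ValueError("negative out-of-pocket spend")
    societal = round(nhs.nhs_pss_total + vat + paid + unpaid + private + oop, 2)
    return CostBreakdown(
        per_category=nhs.per_category,
        intervention=nhs.intervention,
        nhs_pss_total=nhs.nhs_pss_total,
        productivity_paid=paid,
        productivity_unpaid=unpaid,
        private_therapy=private,
        out_of_pocket=oop,
        vat=vat,
        societal_total=societal,
    )
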