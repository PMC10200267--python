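"""Net-monetary-benefit scoring of medical-device tender offers.

A competitive tender lot is described by *fixed parameters* shared by every
bidder — the analysis time horizon, the baseline health-state utility, the
willingness-to-pay (WTP) threshold per QALY, a starting (maximum admissible)
price, and a small set of clinical endpoints each with a disutility, the
duration that disutility persists, and a cost per event. Each *offer*
contributes the device-specific variables: a price and the per-endpoint event
rates observed over the horizon.

The score of an offer is its net monetary benefit (NMB):

    NMB = (u_base - sum_i r_i * d_i * t_i / H) * (H_days / days_per_year) * WTP
          - (price + sum_i r_i * c_i)

i.e. expected quality-adjusted survival over the horizon, monetized at the
WTP threshold, minus expected costs. Quality-adjusted survival is carried in
quality-adjusted life *days* (QALDs) at intermediate steps and converted to
QALYs for reporting. Offers are ranked by decreasing NMB; the top-ranked
admissible offer wins the lot. An optional administrative presentation maps
results onto the conventional 0-30 price / 0-70 quality scales.

The module is laid out in the order a tender evaluation runs:

1. configuration & logging
2. exceptions
3. domain types and their invariants
4. offer validation (admission / exclusion)
5. the eight-step NMB engine
6. ranking
7. two-scale (price/quality) reparameterization
8. file formats: lot JSON, device CSV, report writing
9. packaged example data and the synthetic-tender generator
10. whole-tender orchestration
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DAYS_PER_YEAR_DEFAULT",
    "DeviceOffer",
    "DeviceResult",
    "EndpointSpec",
    "LotParameters",
    "NoAdmissibleOffersError",
    "RunConfig",
    "StepRecord",
    "SyntheticTenderSpec",
    "TenderConfigError",
    "TenderResult",
    "TwoScaleScore",
    "ValidationOutcome",
    "adjust_disutility",
    "baseline_qalds",
    "carotid_stent_fixture",
    "carotid_stent_paths",
    "compute_nmb",
    "disutility_qalds",
    "format_ranking_table",
    "format_step_trace",
    "generate_tender",
    "monetize_benefit",
    "net_qalds",
    "qalds_to_qalys",
    "rank_devices",
    "read_devices",
    "read_lot",
    "run_tender",
    "total_cost",
    "two_scale_scores",
    "validate_offer",
    "write_report",
]

# ---------------------------------------------------------------------------
# 1. configuration & logging
# ---------------------------------------------------------------------------

logger = logging.getLogger("nmbtender")

#: Calendar convention for the QALD <-> QALY conversion.
DAYS_PER_YEAR_DEFAULT = 365.0

#: Default rounding used when rendering reports: quality-adjusted survival
#: (QALDs/QALYs) to 4 decimals, currency to 2.
REPORT_DECIMALS_QUALITY = 4
REPORT_DECIMALS_CURRENCY = 2

RateUnit = Literal["fraction", "percent"]
PriceRule = Literal["proportional", "interpolated"]


def _fmt(value: float, decimals: int) -> str:
    """Render a number with thousands separators, e.g. 51482.8767 -> '51,482.88'."""
    return f"{value:,.{decimals}f}"


# ---------------------------------------------------------------------------
# 2. exceptions
# ---------------------------------------------------------------------------


class TenderConfigError(ValueError):
    """A lot, offer, or input file violates the model's invariants.

    Carries the full list of violations so a user can fix a config file in
    one pass rather than one error at a time.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class NoAdmissibleOffersError(RuntimeError):
    """Raised when every offer in the lot was excluded (or none were given)."""


def _require(violations: list[str], ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


# ---------------------------------------------------------------------------
# 3. domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndpointSpec:
    """One clinical endpoint of the lot, with its fixed parameters.

    Parameters
    ----------
    endpoint_id:
        Short stable identifier used as the CSV column suffix (``rate_<id>``).
    label:
        Free-text description, e.g. ``"minor stroke"``.
    disutility:
        Utility decrement caused by one event, dimensionless in [0, 1].
    duration_months:
        How long the decrement persists, in months; must not exceed the lot
        horizon (checked at lot construction).
    cost_per_event:
        Expected cost of one event, in the lot currency, >= 0.
    """

    endpoint_id: str
    label: str
    disutility: float
    duration_months: float
    cost_per_event: float

    def __post_init__(self):
        v: list[str] = []
        _require(v, bool(self.endpoint_id), "endpoint_id must be non-empty")
        _require(v, 0.0 <= self.disutility <= 1.0,
                 f"endpoint {self.endpoint_id!r}: disutility {self.disutility} outside [0, 1]")
        _require(v, self.duration_months > 0,
                 f"endpoint {self.endpoint_id!r}: duration_months {self.duration_months} must be > 0")
        _require(v, self.cost_per_event >= 0,
                 f"endpoint {self.endpoint_id!r}: cost_per_event {self.cost_per_event} must be >= 0")
        if v:
            raise TenderConfigError(v)


@dataclass(frozen=True)
class LotParameters:
    """Fixed parameters of one tender lot (identical for all bidders)."""

    lot_id: str
    horizon_months: float
    baseline_utility: float
    wtp_per_qaly: float
    starting_price: float
    endpoints: tuple[EndpointSpec, ...]
    days_per_year: float = DAYS_PER_YEAR_DEFAULT
    currency_label: str = "euro"

    def __post_init__(self):
        object.__setattr__(self, "endpoints", tuple(self.endpoints))
        v: list[str] = []
        _require(v, self.horizon_months > 0, f"horizon_months {self.horizon_months} must be > 0")
        _require(v, 0.0 < self.baseline_utility <= 1.0,
                 f"baseline_utility {self.baseline_utility} outside (0, 1]")
        _require(v, self.wtp_per_qaly > 0, f"wtp_per_qaly {self.wtp_per_qaly} must be > 0")
        _require(v, self.starting_price > 0, f"starting_price {self.starting_price} must be > 0")
        _require(v, self.days_per_year > 0, f"days_per_year {self.days_per_year} must be > 0")
        _require(v, 1 <= len(self.endpoints) <= 10,
                 f"lot must define between 1 and 10 endpoints, got {len(self.endpoints)}")
        seen: set[str] = set()
        for ep in self.endpoints:
            if ep.endpoint_id in seen:
                v.append(f"duplicate endpoint_id {ep.endpoint_id!r}")
            seen.add(ep.endpoint_id)
            _require(v, ep.duration_months <= self.horizon_months,
                     f"endpoint {ep.endpoint_id!r}: duration {ep.duration_months} months "
                     f"exceeds the {self.horizon_months}-month horizon")
        if v:
            raise TenderConfigError(v)

    @property
    def horizon_days(self) -> float:
        """Horizon in days: round(days_per_year * months / 12); 12 months -> 365."""
        return float(round(self.days_per_year * self.horizon_months / 12.0))

    @property
    def endpoint_ids(self) -> tuple[str, ...]:
        return tuple(ep.endpoint_id for ep in self.endpoints)


@dataclass(frozen=True)
class DeviceOffer:
    """One bid: device identity, offered price, per-endpoint event rates.

    ``event_rates`` maps endpoint_id to the probability (fraction in [0, 1])
    of that event occurring within the lot horizon. Percent input is
    converted at read time (see :func:`read_devices`); internally rates are
    always fractions.
    """

    device_id: str
    manufacturer: str
    price: float
    event_rates: dict[str, float]

    def __post_init__(self):
        v: list[str] = []
        _require(v, bool(self.device_id), "device_id must be non-empty")
        _require(v, self.price >= 0, f"device {self.device_id!r}: price {self.price} must be >= 0")
        if v:
            raise TenderConfigError(v)


@dataclass(frozen=True)
class StepRecord:
    """One line of the eight-step computation trace."""

    step: int
    description: str
    value: float


@dataclass(frozen=True)
class DeviceResult:
    """Full step trace and final NMB for one admitted offer."""

    device_id: str
    manufacturer: str
    price: float
    qalds_baseline: float
    qalds_disutility: float
    qalds_net: float
    qalys: float
    benefit_money: float
    cost_events: float
    cost_total: float
    nmb: float
    step_trace: tuple[StepRecord, ...]


@dataclass(frozen=True)
class TwoScaleScore:
    """Administrative 0-30 price / 0-70 quality presentation of one result."""

    device_id: str
    price_score: float
    quality_score: float

    @property
    def total_score(self) -> float:
        return self.price_score + self.quality_score


@dataclass(frozen=True)
class ValidationOutcome:
    """Admission decision for one offer.

    ``kind`` distinguishes a price exclusion (a legitimate losing bid) from a
    structural problem (malformed rates or endpoint mismatch) that points at
    a data-entry error.
    """

    device_id: str
    admitted: bool
    kind: Literal["admitted", "price", "rate", "structure"]
    reason: str = ""


@dataclass(frozen=True)
class TenderResult:
    """Outcome of one lot evaluation."""

    lot_id: str
    results: tuple[DeviceResult, ...]
    excluded: tuple[tuple[str, str], ...]
    ranking: tuple[str, ...]
    two_scale: tuple[TwoScaleScore, ...] | None = None

    def result_for(self, device_id: str) -> DeviceResult:
        for r in self.results:
            if r.device_id == device_id:
                return r
        raise KeyError(device_id)


# ---------------------------------------------------------------------------
# 4. offer validation
# ---------------------------------------------------------------------------


def validate_offer(offer: DeviceOffer, lot: LotParameters) -> ValidationOutcome:
    """Decide whether an offer is admitted to the lot.

    Exclusion rules, checked in order:

    * the set of rate keys must exactly match the lot's endpoint ids
      (``kind="structure"``);
    * every rate must lie in [0, 1] (``kind="rate"``) — a rate above 1 is
      usually a percent/fraction unit mix-up;
    * the price must not exceed the starting price (``kind="price"``).
      Offers exactly at the starting price are admitted.

    Validation is deterministic and depends only on the single offer and the
    lot, never on the other offers.
    """
    lot_ids = set(lot.endpoint_ids)
    offer_ids = set(offer.event_rates)
    if offer_ids != lot_ids:
        missing = sorted(lot_ids - offer_ids)
        extra = sorted(offer_ids - lot_ids)
        parts = []
        if missing:
            parts.append(f"missing rates for {missing}")
        if extra:
            parts.append(f"unknown endpoints {extra}")
        return ValidationOutcome(offer.device_id, False, "structure",
                                 f"endpoint mismatch: {'; '.join(parts)}")
    for eid in lot.endpoint_ids:
        r = offer.event_rates[eid]
        if not (0.0 <= r <= 1.0):
            return ValidationOutcome(
                offer.device_id, False, "rate",
                f"rate {r} for endpoint {eid!r} outside [0, 1] "
                f"(check the rate_unit setting)")
    if offer.price > lot.starting_price:
        return ValidationOutcome(
            offer.device_id, False, "price",
            f"price {offer.price} exceeds the starting price {lot.starting_price}")
    return ValidationOutcome(offer.device_id, True, "admitted")


# ---------------------------------------------------------------------------
# 5. the eight-step NMB engine
# ---------------------------------------------------------------------------


def adjust_disutility(real_disutility: float, real_duration: float, horizon: float) -> float:
    """Normalize a transient utility loss onto the analysis horizon.

        adjusted = real_disutility * real_duration / horizon

    A utility loss of 0.30 lasting 1 month equals, over a 12-month horizon,
    a constant disutility of 0.025; equally, (0.50, 1 month) and
    (0.25, 2 months) are interchangeable. The disutility cannot persist
    beyond the horizon.
    """
    if not (0.0 <= real_disutility <= 1.0):
        raise ValueError(f"disutility {real_disutility} outside [0, 1]")
    if real_duration <= 0:
        raise ValueError(f"duration {real_duration} must be > 0")
    if real_duration > horizon:
        raise ValueError(
            f"duration {real_duration} months exceeds the {horizon}-month horizon")
    # d * (t/h) rather than d*t/h: keeps the identity exact when the
    # duration spans the whole horizon (t/h == 1.0).
    return real_disutility * (real_duration / horizon)


def baseline_qalds(lot: LotParameters) -> float:
    """Quality-adjusted life days over the horizon if no event occurs."""
    return lot.baseline_utility * lot.horizon_days


def disutility_qalds(lot: LotParameters, offer: DeviceOffer) -> float:
    """Expected QALDs lost to endpoint events.

    Each endpoint contributes rate x horizon-adjusted disutility x horizon
    days; contributions sum because rates are expectations, not a patient
    pathway.
    """
    total = 0.0
    for ep in lot.endpoints:
        adj = adjust_disutility(ep.disutility, ep.duration_months, lot.horizon_months)
        total += offer.event_rates[ep.endpoint_id] * adj * lot.horizon_days
    return total


def net_qalds(baseline: float, disutility: float) -> float:
    """Baseline minus event disutility, clamped at zero.

    A negative net quality-adjusted survival has no interpretation in this
    model; it can only arise from implausible inputs, so it is clamped to 0
    with a warning rather than raised.
    """
    net = baseline - disutility
    if net < 0:
        logger.warning(
            "net QALDs negative (%.4f baseline - %.4f disutility); clamping to 0 "
            "- check the event rates and disutilities", baseline, disutility)
        return 0.0
    return net


def qalds_to_qalys(qalds: float, days_per_year: float = DAYS_PER_YEAR_DEFAULT) -> float:
    """Convert quality-adjusted life days to quality-adjusted life years."""
    if days_per_year <= 0:
        raise ValueError(f"days_per_year {days_per_year} must be > 0")
    return qalds / days_per_year


def monetize_benefit(qalds: float, lot: LotParameters) -> float:
    """Convert QALDs to currency at the willingness-to-pay threshold."""
    return qalds / lot.days_per_year * lot.wtp_per_qaly


def total_cost(lot: LotParameters, offer: DeviceOffer, include_price: bool = True) -> float:
    """Expected cost: per-endpoint event costs, plus the offered price.

    ``include_price=False`` restricts the cost side to the clinical events
    alone; the default keeps the price in, so that a cheaper device with the
    same outcomes scores strictly higher.
    """
    cost = sum(offer.event_rates[ep.endpoint_id] * ep.cost_per_event for ep in lot.endpoints)
    if include_price:
        cost += offer.price
    return cost


def compute_nmb(lot: LotParameters, offer: DeviceOffer, include_price: bool = True) -> DeviceResult:
    """Run the eight-step pipeline for one admitted offer.

    Steps: (1) horizon, (2) baseline QALDs, (3) disutility QALDs,
    (4) net QALDs (and QALYs), (5) monetized benefit at the WTP threshold,
    (6) total expected costs, (7) benefit minus costs, (8) the NMB.
    The trace stores full-precision values; rounding happens only at
    rendering time.
    """
    base = baseline_qalds(lot)
    disut = disutility_qalds(lot, offer)
    net = net_qalds(base, disut)
    qalys = qalds_to_qalys(net, lot.days_per_year)
    benefit = monetize_benefit(net, lot)
    cost = total_cost(lot, offer, include_price=include_price)
    nmb = benefit - cost
    cur = lot.currency_label
    cost_desc = "Expected costs of endpoint events"
    if include_price:
        cost_desc += " plus the offered price"
    trace = (
        StepRecord(1, "Time horizon (months)", lot.horizon_months),
        StepRecord(2, "Quality-adjusted survival at baseline utility, "
                      "no events (QALDs)", base),
        StepRecord(3, "Expected disutility from endpoint events (QALDs)", disut),
        StepRecord(4, "Net quality-adjusted survival (QALDs)", net),
        StepRecord(5, f"Benefit monetized at the WTP threshold ({cur})", benefit),
        StepRecord(6, f"{cost_desc} ({cur})", cost),
        StepRecord(7, f"Benefit minus costs ({cur})", nmb),
        StepRecord(8, f"Net monetary benefit ({cur})", nmb),
    )
    return DeviceResult(
        device_id=offer.device_id,
        manufacturer=offer.manufacturer,
        price=offer.price,
        qalds_baseline=base,
        qalds_disutility=disut,
        qalds_net=net,
        qalys=qalys,
        benefit_money=benefit,
        cost_events=cost - (offer.price if include_price else 0.0),
        cost_total=cost,
        nmb=nmb,
        step_trace=trace,
    )


# ---------------------------------------------------------------------------
# 6. ranking
# ---------------------------------------------------------------------------


def rank_devices(results: Sequence[DeviceResult]) -> list[str]:
    """Order device ids by decreasing NMB; the first listed device wins.

    Ties are broken deterministically: equal NMB -> lower price first;
    still equal -> lexicographic device_id. The result never depends on the
    input order.
    """
    if not results:
        raise NoAdmissibleOffersError("no admissible offers to rank")
    ordered = sorted(results, key=lambda r: (-r.nmb, r.price, r.device_id))
    return [r.device_id for r in ordered]


# ---------------------------------------------------------------------------
# 7. two-scale (price/quality) reparameterization
# ---------------------------------------------------------------------------


def two_scale_scores(
    results: Sequence[DeviceResult],
    lot: LotParameters,
    price_rule: PriceRule = "proportional",
) -> list[TwoScaleScore]:
    """Map results onto the conventional 0-30 price / 0-70 quality scales.

    Price score (best-priced device always gets exactly 30):

    * ``proportional``: 30 * lowest price / device price;
    * ``interpolated``: linear between the starting price (0 points) and the
      lowest offered price (30 points).

    Quality score: 70 * q / max(q), where q is the device's monetized benefit
    net of event costs but *excluding* its price (the price already scored on
    the other scale). The best-quality device gets exactly 70. Scores are
    clipped to their scales.

    This presentation is an administrative convention layered on top of the
    NMB; with weights fixed at 30/70 it can in principle rank devices
    differently from the raw NMB, which is why :func:`run_tender` logs a
    warning when the two orders disagree rather than hiding it.
    """
    if not results:
        raise NoAdmissibleOffersError("no admissible offers to score")
    prices = [r.price for r in results]
    if min(prices) <= 0:
        raise ValueError("two-scale scoring requires strictly positive prices")
    p_min = min(prices)
    quality = [r.benefit_money - r.cost_events for r in results]
    q_max = max(quality)
    if q_max <= 0:
        raise ValueError(
            "two-scale scoring is undefined when no device has a positive "
            "monetized benefit net of event costs; score on the raw NMB scale instead")
    scores = []
    for r, q in zip(results, quality):
        if price_rule == "proportional":
            ps = 30.0 * p_min / r.price
        elif price_rule == "interpolated":
            span = lot.starting_price - p_min
            ps = 30.0 if span <= 0 else 30.0 * (lot.starting_price - r.price) / span
        else:
            raise ValueError(f"unknown price rule {price_rule!r}")
        qs = 70.0 * q / q_max
        scores.append(TwoScaleScore(
            device_id=r.device_id,
            price_score=min(max(ps, 0.0), 30.0),
            quality_score=min(max(qs, 0.0), 70.0),
        ))
    return scores


# ---------------------------------------------------------------------------
# 8. file formats and reports
# ---------------------------------------------------------------------------

_LOT_REQUIRED = {
    "lot_id": str,
    "horizon_months": (int, float),
    "baseline_utility": (int, float),
    "wtp_per_qaly": (int, float),
    "starting_price": (int, float),
    "endpoints": list,
}
_ENDPOINT_REQUIRED = {
    "endpoint_id": str,
    "label": str,
    "disutility": (int, float),
    "duration_months": (int, float),
    "cost_per_event": (int, float),
}


def read_lot(path: str | Path) -> LotParameters:
    """Read and validate a lot configuration from a JSON file.

    All schema violations are collected and reported together, each with the
    offending field path.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise TenderConfigError([f"{path}: file is empty"])
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TenderConfigError([f"{path}: not valid JSON: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise TenderConfigError([f"{path}: top level must be a JSON object"])

    v: list[str] = []
    for key, typ in _LOT_REQUIRED.items():
        if key not in raw:
            v.append(f"{key}: missing required field")
        elif not isinstance(raw[key], typ) or isinstance(raw[key], bool):
            v.append(f"{key}: expected {getattr(typ, '__name__', 'number')}, "
                     f"got {type(raw[key]).__name__}")
    endpoints: list[EndpointSpec] = []
    for i, ep in enumerate(raw.get("endpoints") or []):
        where = f"endpoints[{i}]"
        if not isinstance(ep, dict):
            v.append(f"{where}: expected an object")
            continue
        ep_v: list[str] = []
        for key, typ in _ENDPOINT_REQUIRED.items():
            if key not in ep:
                ep_v.append(f"{where}.{key}: missing required field")
            elif not isinstance(ep[key], typ) or isinstance(ep[key], bool):
                ep_v.append(f"{where}.{key}: expected {getattr(typ, '__name__', 'number')}, "
                            f"got {type(ep[key]).__name__}")
        if ep_v:
            v.extend(ep_v)
            continue
        try:
            endpoints.append(EndpointSpec(
                endpoint_id=ep["endpoint_id"],
                label=ep["label"],
                disutility=float(ep["disutility"]),
                duration_months=float(ep["duration_months"]),
                cost_per_event=float(ep["cost_per_event"]),
            ))
        except TenderConfigError as exc:
            v.extend(f"{where}: {msg}" for msg in exc.violations)
    if v:
        raise TenderConfigError([f"{path}: {msg}" for msg in v])
    try:
        return LotParameters(
            lot_id=raw["lot_id"],
            horizon_months=float(raw["horizon_months"]),
            baseline_utility=float(raw["baseline_utility"]),
            wtp_per_qaly=float(raw["wtp_per_qaly"]),
            starting_price=float(raw["starting_price"]),
            endpoints=tuple(endpoints),
            days_per_year=float(raw.get("days_per_year", DAYS_PER_YEAR_DEFAULT)),
            currency_label=raw.get("currency_label", "euro"),
        )
    except TenderConfigError as exc:
        raise TenderConfigError([f"{path}: {msg}" for msg in exc.violations]) from exc


def write_lot(lot: LotParameters, path: str | Path) -> None:
    """Write a lot back to the JSON format :func:`read_lot` accepts."""
    payload = {
        "lot_id": lot.lot_id,
        "horizon_months": lot.horizon_months,
        "baseline_utility": lot.baseline_utility,
        "wtp_per_qaly": lot.wtp_per_qaly,
        "starting_price": lot.starting_price,
        "days_per_year": lot.days_per_year,
        "currency_label": lot.currency_label,
        "endpoints": [
            {
                "endpoint_id": ep.endpoint_id,
                "label": ep.label,
                "disutility": ep.disutility,
                "duration_months": ep.duration_months,
                "cost_per_event": ep.cost_per_event,
            }
            for ep in lot.endpoints
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_devices(
    path: str | Path,
    rate_unit: RateUnit = "fraction",
    endpoint_ids: Sequence[str] | None = None,
) -> list[DeviceOffer]:
    """Read device offers from CSV.

    Expected header: ``device_id,manufacturer,price,rate_<endpoint_id>,...``.
    With ``rate_unit="percent"`` every rate cell is divided by 100 (the
    tender documents this model comes from print rates like "2.35%").
    Passing the lot's ``endpoint_ids`` makes unknown or missing rate columns
    a file-level error instead of a downstream validation failure.
    """
    path = Path(path)
    if rate_unit not in ("fraction", "percent"):
        raise ValueError(f"rate_unit must be 'fraction' or 'percent', got {rate_unit!r}")
    v: list[str] = []
    offers: list[DeviceOffer] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("device_id", "manufacturer", "price"):
            if col not in header:
                v.append(f"{path}: missing required column {col!r}")
        rate_cols = [c for c in header if c.startswith("rate_")]
        if not rate_cols:
            v.append(f"{path}: no rate_<endpoint_id> columns found")
        if endpoint_ids is not None:
            have = {c[len("rate_"):] for c in rate_cols}
            want = set(endpoint_ids)
            for eid in sorted(want - have):
                v.append(f"{path}: missing rate column for endpoint {eid!r}")
            for eid in sorted(have - want):
                v.append(f"{path}: unknown rate column 'rate_{eid}'")
        if v:
            raise TenderConfigError(v)
        for row_no, row in enumerate(reader, start=2):
            rates: dict[str, float] = {}
            row_bad = False
            for col in rate_cols:
                cell = (row.get(col) or "").strip()
                try:
                    value = float(cell)
                except ValueError:
                    v.append(f"{path}: row {row_no}: non-numeric rate {cell!r} in {col!r}")
                    row_bad = True
                    continue
                rates[col[len("rate_"):]] = value / 100.0 if rate_unit == "percent" else value
            try:
                price = float((row.get("price") or "").strip())
            except ValueError:
                v.append(f"{path}: row {row_no}: non-numeric price {row.get('price')!r}")
                row_bad = True
                price = math.nan
            if row_bad:
                continue
            try:
                offers.append(DeviceOffer(
                    device_id=(row.get("device_id") or "").strip(),
                    manufacturer=(row.get("manufacturer") or "").strip(),
                    price=price,
                    event_rates=rates,
                ))
            except TenderConfigError as exc:
                v.extend(f"{path}: row {row_no}: {msg}" for msg in exc.violations)
    if v:
        raise TenderConfigError(v)
    if not offers:
        raise TenderConfigError([f"{path}: no offers found (empty CSV body)"])
    return offers


def write_devices(offers: Sequence[DeviceOffer], path: str | Path,
                  endpoint_ids: Sequence[str]) -> None:
    """Write offers back to the CSV format :func:`read_devices` accepts (fractions)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "manufacturer", "price"]
                        + [f"rate_{eid}" for eid in endpoint_ids])
        for o in offers:
            writer.writerow([o.device_id, o.manufacturer, repr(o.price)]
                            + [repr(o.event_rates[eid]) for eid in endpoint_ids])


def format_step_trace(result: DeviceResult, lot: LotParameters,
                      decimals: int | None = None) -> str:
    """Render one device's eight-step trace as an aligned text table.

    QALD/QALY quantities print with 4 decimals and currency with 2 unless a
    single override is given.
    """
    dq = decimals if decimals is not None else REPORT_DECIMALS_QUALITY
    dc = decimals if decimals is not None else REPORT_DECIMALS_CURRENCY
    lines = [f"Device: {result.device_id} ({result.manufacturer}) — "
             f"price {_fmt(result.price, dc)} {lot.currency_label}"]
    for rec in result.step_trace:
        if rec.step == 1:
            value = f"{rec.value:g} months"
        elif rec.step in (2, 3):
            value = f"QALDs={_fmt(rec.value, dq)}"
        elif rec.step == 4:
            value = (f"QALDs={_fmt(rec.value, dq)}, "
                     f"i.e., QALYs={_fmt(result.qalys, dq)}")
        else:
            value = f"{_fmt(rec.value, dc)} {lot.currency_label}"
        lines.append(f"  {rec.step}. {rec.description:<68s} {value}")
    return "\n".join(lines)


def format_ranking_table(tender: TenderResult, lot: LotParameters,
                         decimals: int | None = None) -> str:
    """Render the final classification (and two-scale scores, if computed)."""
    dc = decimals if decimals is not None else REPORT_DECIMALS_CURRENCY
    two = {s.device_id: s for s in tender.two_scale} if tender.two_scale else {}
    head = f"{'rank':>4}  {'device_id':<16} {'manufacturer':<18} {'price':>12} {'NMB':>16}"
    if two:
        head += f" {'price/30':>9} {'quality/70':>10} {'total/100':>10}"
    lines = [head]
    for i, device_id in enumerate(tender.ranking, start=1):
        r = tender.result_for(device_id)
        line = (f"{i:>4}  {r.device_id:<16} {r.manufacturer:<18} "
                f"{_fmt(r.price, dc):>12} {_fmt(r.nmb, dc):>16}")
        if two:
            s = two[device_id]
            line += (f" {s.price_score:>9.2f} {s.quality_score:>10.2f}"
                     f" {s.total_score:>10.2f}")
        lines.append(line)
    if tender.excluded:
        lines.append("")
        lines.append("Excluded offers:")
        for device_id, reason in tender.excluded:
            lines.append(f"  {device_id}: {reason}")
    return "\n".join(lines)


@dataclass
class RunConfig:
    """Everything one CLI invocation needs; owns the run's random seed."""

    lot_path: str | Path
    devices_path: str | Path
    rate_unit: RateUnit = "fraction"
    include_price: bool = True
    two_scale: bool = False
    price_rule: PriceRule = "proportional"
    decimals: int | None = None
    out_dir: str | Path = "nmbtender-out"
    verbosity: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.decimals is not None and not (0 <= self.decimals <= 6):
            raise TenderConfigError([f"decimals {self.decimals} outside 0-6"])


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(tender: TenderResult, lot: LotParameters, config: RunConfig) -> list[Path]:
    """Write the tender report files into ``config.out_dir``.

    Produces ``report.txt`` (per-device traces + ranking + exclusions),
    ``ranking.csv``, ``steps.csv`` (long-format traces), and
    ``run_summary.json`` (input digests, config, package version) for audit.
    Output is byte-stable for identical inputs and config.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise TenderConfigError([f"output directory {out} is not writable: {exc}"]) from exc

    sections = [f"Lot: {tender.lot_id} — net-monetary-benefit tender evaluation", ""]
    for device_id in tender.ranking:
        sections.append(format_step_trace(tender.result_for(device_id), lot, config.decimals))
        sections.append("")
    sections.append(format_ranking_table(tender, lot, config.decimals))
    report_txt = out / "report.txt"
    report_txt.write_text("\n".join(sections) + "\n")

    ranking_csv = out / "ranking.csv"
    with ranking_csv.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["rank", "device_id", "manufacturer", "price", "nmb"]
        if tender.two_scale:
            header += ["price_score", "quality_score", "total_score"]
        writer.writerow(header)
        two = {s.device_id: s for s in tender.two_scale} if tender.two_scale else {}
        for i, device_id in enumerate(tender.ranking, start=1):
            r = tender.result_for(device_id)
            row = [i, r.device_id, r.manufacturer, repr(r.price), repr(r.nmb)]
            if two:
                s = two[device_id]
                row += [repr(s.price_score), repr(s.quality_score), repr(s.total_score)]
            writer.writerow(row)

    steps_csv = out / "steps.csv"
    with steps_csv.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "step", "description", "value"])
        for r in tender.results:
            for rec in r.step_trace:
                writer.writerow([r.device_id, rec.step, rec.description, repr(rec.value)])

    summary = {
        "package": "nmbtender",
        "version": __version__,
        "lot_id": tender.lot_id,
        "inputs": {
            "lot": {"path": str(config.lot_path), "sha256": _sha256(config.lot_path)},
            "devices": {"path": str(config.devices_path), "sha256": _sha256(config.devices_path)},
        },
        "config": {
            "rate_unit": config.rate_unit,
            "include_price": config.include_price,
            "two_scale": config.two_scale,
            "price_rule": config.price_rule,
            "decimals": config.decimals,
            "seed": config.seed,
        },
        "ranking": list(tender.ranking),
        "excluded": [list(pair) for pair in tender.excluded],
    }
    summary_json = out / "run_summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [report_txt, ranking_csv, steps_csv, summary_json]


# ---------------------------------------------------------------------------
# 9. packaged example data and the synthetic-tender generator
# ---------------------------------------------------------------------------


def carotid_stent_paths() -> tuple[Path, Path]:
    """Paths of the packaged carotid-stent example (lot JSON, devices CSV)."""
    data = resources.files("nmbtender") / "data"
    return Path(str(data / "carotid_lot.json")), Path(str(data / "carotid_devices.csv"))


def carotid_stent_fixture() -> tuple[LotParameters, list[DeviceOffer]]:
    """The packaged carotid-stent tender: three devices, three endpoints.

    A 2021 Italian tender for carotid-endarterectomy stents: endpoints minor
    stroke / major stroke / death over a 12-month horizon, WTP 60,000
    euro/QALY, baseline utility 0.93, with published 12-month event rates and
    price offers for devices by Abbott, Cardinal Health, and Medtronic.

    The per-endpoint disutilities, durations and costs of the original lot
    were never published; the values shipped here are NON-AUTHORITATIVE
    calibration artifacts, back-solved so the model reproduces the winning
    device's published NMB exactly (see ``data/carotid_notes.md``). Rates in
    the CSV are stored as percentages, as the source prints them.
    """
    lot_path, dev_path = carotid_stent_paths()
    lot = read_lot(lot_path)
    offers = read_devices(dev_path, rate_unit="percent", endpoint_ids=lot.endpoint_ids)
    return lot, offers


@dataclass(frozen=True)
class SyntheticTenderSpec:
    """Ranges for the seeded random-tender generator used by property tests.

    Defaults describe a realistic advanced-device lot: a 12-month horizon,
    high baseline utility, WTP thresholds spanning common international
    standards, low event rates (high-risk devices do not reach tenders), and
    a configurable fraction of offers priced above the starting price so the
    exclusion path is exercised.
    """

    n_devices: int = 3
    n_endpoints: int = 3
    horizon_months: float = 12.0
    utility_range: tuple[float, float] = (0.70, 1.0)
    wtp_range: tuple[float, float] = (20_000.0, 100_000.0)
    rate_range: tuple[float, float] = (0.0, 0.05)
    disutility_range: tuple[float, float] = (0.05, 0.95)
    duration_range: tuple[float, float] = (1.0, 12.0)
    cost_range: tuple[float, float] = (0.0, 50_000.0)
    price_range: tuple[float, float] = (200.0, 1_000.0)
    starting_price: float = 1_000.0
    overpriced_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        v: list[str] = []
        _require(v, self.n_devices >= 1, "n_devices must be >= 1")
        _require(v, 1 <= self.n_endpoints <= 10, "n_endpoints must be in 1..10")
        for name in ("utility_range", "wtp_range", "rate_range", "disutility_range",
                     "duration_range", "cost_range", "price_range"):
            lo, hi = getattr(self, name)
            _require(v, lo <= hi, f"{name}: lower bound {lo} exceeds upper bound {hi}")
        _require(v, 0.0 < self.utility_range[0] and self.utility_range[1] <= 1.0,
                 "utility_range must lie in (0, 1]")
        _require(v, 0.0 <= self.rate_range[0] and self.rate_range[1] <= 1.0,
                 "rate_range must lie in [0, 1]")
        _require(v, 0.0 <= self.disutility_range[0] and self.disutility_range[1] <= 1.0,
                 "disutility_range must lie in [0, 1]")
        _require(v, 0.0 < self.duration_range[0]
                 and self.duration_range[1] <= self.horizon_months,
                 "duration_range must lie in (0, horizon_months]")
        _require(v, self.wtp_range[0] > 0, "wtp_range must be positive")
        _require(v, self.cost_range[0] >= 0, "cost_range must be non-negative")
        _require(v, self.price_range[0] >= 0, "price_range must be non-negative")
        _require(v, self.price_range[1] <= self.starting_price,
                 "price_range upper bound must not exceed the starting price")
        _require(v, 0.0 <= self.overpriced_fraction <= 1.0,
                 "overpriced_fraction must lie in [0, 1]")
        # Worst case disutility per endpoint is rate * disutility (duration at
        # the horizon); net QALDs stay positive iff the sum cannot reach the
        # baseline utility.
        worst = self.n_endpoints * self.rate_range[1] * self.disutility_range[1]
        _require(v, worst < self.utility_range[0],
                 f"infeasible ranges: worst-case disutility {worst:.3f} can exceed "
                 f"the minimum baseline utility {self.utility_range[0]}")
        if v:
            raise TenderConfigError(v)


def generate_tender(spec: SyntheticTenderSpec) -> tuple[LotParameters, list[DeviceOffer]]:
    """Draw one random tender satisfying every domain invariant.

    Reproducible: the same spec (including its seed) always yields the same
    lot and offers. A fraction of offers is deliberately priced above the
    starting price so downstream validation has exclusions to exercise.
    """
    rng = np.random.default_rng(spec.seed)
    endpoints = tuple(
        EndpointSpec(
            endpoint_id=f"ep{i}",
            label=f"synthetic endpoint {i}",
            disutility=float(rng.uniform(*spec.disutility_range)),
            duration_months=float(rng.uniform(*spec.duration_range)),
            cost_per_event=float(rng.uniform(*spec.cost_range)),
        )
        for i in range(spec.n_endpoints)
    )
    lot = LotParameters(
        lot_id=f"synthetic-{spec.seed}",
        horizon_months=spec.horizon_months,
        baseline_utility=float(rng.uniform(*spec.utility_range)),
        wtp_per_qaly=float(rng.uniform(*spec.wtp_range)),
        starting_price=spec.starting_price,
        endpoints=endpoints,
    )
    offers = []
    for j in range(spec.n_devices):
        if rng.uniform() < spec.overpriced_fraction:
            price = float(rng.uniform(spec.starting_price * (1 + 1e-9),
                                      spec.starting_price * 1.5))
        else:
            price = float(rng.uniform(*spec.price_range))
        offers.append(DeviceOffer(
            device_id=f"dev{j}",
            manufacturer=f"synthetic manufacturer {j}",
            price=price,
            event_rates={ep.endpoint_id: float(rng.uniform(*spec.rate_range))
                         for ep in endpoints},
        ))
    return lot, offers


# ---------------------------------------------------------------------------
# 10. whole-tender orchestration
# ---------------------------------------------------------------------------


def run_tender(
    lot: LotParameters,
    offers: Sequence[DeviceOffer],
    include_price: bool = True,
    two_scale: bool = False,
    price_rule: PriceRule = "proportional",
) -> TenderResult:
    """Validate every offer, score the admitted ones, and rank them.

    Raises :class:`NoAdmissibleOffersError` if every offer is excluded.
    When ``two_scale`` is set the 0-30/0-70 presentation is appended, and a
    warning is logged if it would rank the devices differently from the NMB.
    """
    seen: set[str] = set()
    for o in offers:
        if o.device_id in seen:
            raise TenderConfigError([f"duplicate device_id {o.device_id!r}"])
        seen.add(o.device_id)

    results: list[DeviceResult] = []
    excluded: list[tuple[str, str]] = []
    for offer in offers:
        outcome = validate_offer(offer, lot)
        if outcome.admitted:
            results.append(compute_nmb(lot, offer, include_price=include_price))
        else:
            logger.info("excluding %s: %s", offer.device_id, outcome.reason)
            excluded.append((offer.device_id, outcome.reason))
    if not results:
        raise NoAdmissibleOffersError(
            f"lot {lot.lot_id!r}: no admissible offers "
            f"({len(excluded)} excluded)")
    ranking = rank_devices(results)

    scores = None
    if two_scale:
        scores = tuple(two_scale_scores(results, lot, price_rule=price_rule))
        by_total = sorted(scores, key=lambda s: (-s.total_score, s.device_id))
        if [s.device_id for s in by_total] != ranking:
            logger.warning(
                "two-scale (30/70) ranking differs from the NMB ranking: %s vs %s",
                [s.device_id for s in by_total], ranking)

    return TenderResult(
        lot_id=lot.lot_id,
        results=tuple(results),
        excluded=tuple(excluded),
        ranking=tuple(ranking),
        two_scale=scores,
    )
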