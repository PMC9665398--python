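"""Discrete-choice design: car offers, scenarios, and currency conventions.

The survey's price-sensitivity section presents every participant with
pairwise choices between two driverless cars, each defined by a collision
programming model and a price.  Three programming models crossed with three
price points give 9 distinct offers; the canonical design enumerates all
C(9,2) = 36 unordered pairs of distinct offers.

All prices are carried internally in thousands of pounds (£k), the same
scale on which programme utilities are expressed, so that a utility of
-10.7 reads directly as "worth £10,700 less than the reference programme".
Yen appear only at the I/O boundary, converted at the 150 ¥/£ rate implied
by the survey's printed price lists (¥2,250,000 ↔ £15,000).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

__all__ = [
    "Program",
    "Currency",
    "Country",
    "Frame",
    "Condition",
    "CarOffer",
    "ChoiceScenario",
    "ChoiceRecord",
    "PreferenceResponse",
    "LikertResponse",
    "CANONICAL_PRICES",
    "generate_choice_design",
    "convert_price",
    "YEN_PER_POUND",
]

#: Canonical price grid in £k.
CANONICAL_PRICES = (15.0, 19.0, 23.0)

#: Exchange rate implied by the paired GBP/JPY price lists.
YEN_PER_POUND = 150_000 / 1_000  # 150 ¥ per £


class Program(str, enum.Enum):
    """Collision programming model of a driverless car."""

    MOST = "MOST"  # save the greater number of people (reference)
    OCCUPANTS = "OCCUPANTS"
    PEDESTRIANS = "PEDESTRIANS"


class Currency(str, enum.Enum):
    GBP = "GBP"
    JPY = "JPY"


class Country(str, enum.Enum):
    UK = "UK"
    JP = "JP"


class Frame(str, enum.Enum):
    """Framing under which the algorithm-preference question was asked."""

    UNFRAMED = "UNFRAMED"
    FAMILY_PASSENGER = "FAMILY_PASSENGER"
    FAMILY_PEDESTRIAN = "FAMILY_PEDESTRIAN"
    MORAL = "MORAL"


class Condition(str, enum.Enum):
    """Mandate condition of a 1-7 purchase-willingness question."""

    BASELINE = "BASELINE"
    MANDATE_MOST = "MANDATE_MOST"
    MANDATE_PED = "MANDATE_PED"
    MANDATE_OCC = "MANDATE_OCC"


class PreferenceChoice(str, enum.Enum):
    """Algorithm selected in a categorical preference question."""

    MOST = "MOST"
    OCCUPANTS = "OCCUPANTS"
    PEDESTRIANS = "PEDESTRIANS"
    RANDOM = "RANDOM"


@dataclass(frozen=True, order=True)
class CarOffer:
    """A candidate vehicle: programming model plus price in £k."""

    program: Program
    price: float

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError(f"price must be positive, got {self.price}")


@dataclass(frozen=True)
class ChoiceScenario:
    """One binary choice task: car A versus car B."""

    scenario_id: int
    car_a: CarOffer
    car_b: CarOffer

    def __post_init__(self) -> None:
        if self.car_a == self.car_b:
            raise ValueError("car_a and car_b must differ in program or price")


@dataclass(frozen=True)
class ChoiceRecord:
    """One participant's decision on one scenario."""

    participant_id: str
    country: Country
    scenario_id: int
    choice: str  # "A" or "B"

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ValueError(f"choice must be 'A' or 'B', got {self.choice!r}")


@dataclass(frozen=True)
class PreferenceResponse:
    """Algorithm preference of one participant under one framing."""

    participant_id: str
    country: Country
    frame: Frame
    choice: PreferenceChoice


@dataclass(frozen=True)
class LikertResponse:
    """1-7 purchase willingness of one participant under one condition."""

    participant_id: str
    country: Country
    condition: Condition
    response: int

    def __post_init__(self) -> None:
        if not 1 <= self.response <= 7:
            raise ValueError(f"response must be in 1..7, got {self.response}")


# Sort programs in declaration order (MOST < OCCUPANTS < PEDESTRIANS).
_PROGRAM_ORDER = {p: i for i, p in enumerate(Program)}


def generate_choice_design(prices: tuple[float, ...] = CANONICAL_PRICES) -> list[ChoiceScenario]:
    """Enumerate the canonical discrete-choice design.

    Returns every unordered pair of distinct offers from the
    3 programs x ``len(prices)`` grid, in a fixed deterministic order:
    offers sorted by (program, price), pairs in lexicographic order, and
    1-based scenario ids.  With the canonical three prices this yields the
    survey's 36 scenarios.
    """
    offers = sorted(
        (CarOffer(program, price) for program in Program for price in prices),
        key=lambda o: (_PROGRAM_ORDER[o.program], o.price),
    )
    return [
        ChoiceScenario(scenario_id=i, car_a=a, car_b=b)
        for i, (a, b) in enumerate(itertools.combinations(offers, 2), start=1)
    ]


def convert_price(amount: float, currency: Currency | str) -> float:
    """Convert a raw survey price to the internal £k scale.

    GBP amounts are divided by 1 000; JPY amounts by 150 000 (the exchange
    rate implied by the survey's matched price lists).
    """
    if amount <= 0:
        raise ValueError(f"amount must be positive, got {amount}")
    currency = Currency(currency)
    if currency is Currency.GBP:
        return amount / 1_000
    return amount / 150_000
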