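"""Delimited-text readers and writers for the three survey tables.

Formats (all UTF-8, comma-delimited, mandatory header row):

``choices.csv``
    participant_id, country, scenario_id, model_a, price_a, model_b,
    price_b, currency, choice.  Prices are whole pounds or whole yen as
    indicated by ``currency``; they are converted to £k on read.

``preferences.csv``
    participant_id, country, frame, choice.

``likert.csv``
    participant_id, country, condition, response.

Malformed rows raise :class:`ParseError` carrying the 1-based file line
number of the offending row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .design import (
    CarOffer,
    ChoiceRecord,
    ChoiceScenario,
    Condition,
    Country,
    Currency,
    Frame,
    LikertResponse,
    PreferenceChoice,
    PreferenceResponse,
    Program,
    convert_price,
)

__all__ = [
    "ParseError",
    "read_choice_table",
    "write_choice_table",
    "read_preference_table",
    "write_preference_table",
    "read_likert_table",
    "write_likert_table",
    "choices_to_frame",
]

logger = logging.getLogger(__name__)

_CHOICE_COLUMNS = [
    "participant_id",
    "country",
    "scenario_id",
    "model_a",
    "price_a",
    "model_b",
    "price_b",
    "currency",
    "choice",
]
_PREFERENCE_COLUMNS = ["participant_id", "country", "frame", "choice"]
_LIKERT_COLUMNS = ["participant_id", "country", "condition", "response"]


class ParseError(ValueError):
    """A survey table row violated the format; ``line`` is 1-based."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


def _load(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def _parse_enum(cls, value: str, column: str, line: int):
    try:
        return cls(value)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise ParseError(
            f"invalid {column} {value!r}; expected one of: {valid}", line
        ) from None


def read_choice_table(path: str | Path) -> tuple[list[ChoiceScenario], list[ChoiceRecord]]:
    """Read a choices table; returns (scenarios, records).

    Scenarios are reconstructed from the per-row car attributes and must be
    consistent: the same ``scenario_id`` may not describe two different
    offer pairs.
    """
    df = _load(path, _CHOICE_COLUMNS)
    scenarios: dict[int, ChoiceScenario] = {}
    records: list[ChoiceRecord] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        try:
            scenario_id = int(row.scenario_id)
        except ValueError:
            raise ParseError(f"scenario_id {row.scenario_id!r} is not an integer", line) from None
        country = _parse_enum(Country, row.country, "country", line)
        currency = _parse_enum(Currency, row.currency, "currency", line)
        prog_a = _parse_enum(Program, row.model_a, "model_a", line)
        prog_b = _parse_enum(Program, row.model_b, "model_b", line)
        try:
            price_a = convert_price(float(row.price_a), currency)
            price_b = convert_price(float(row.price_b), currency)
        except ValueError as exc:
            raise ParseError(str(exc), line) from None
        if row.choice not in ("A", "B"):
            raise ParseError(f"invalid choice {row.choice!r}; expected A or B", line)
        try:
            scenario = ChoiceScenario(scenario_id, CarOffer(prog_a, price_a), CarOffer(prog_b, price_b))
        except ValueError as exc:
            raise ParseError(str(exc), line) from None
        if scenario_id in scenarios:
            if scenarios[scenario_id] != scenario:
                raise ParseError(
                    f"scenario_id {scenario_id} redefined with different offers", line
                )
        else:
            scenarios[scenario_id] = scenario
        key = (row.participant_id, scenario_id)
        if key in seen:
            raise ParseError(
                f"duplicate response for participant {row.participant_id!r} "
                f"scenario {scenario_id}",
                line,
            )
        seen.add(key)
        records.append(ChoiceRecord(row.participant_id, country, scenario_id, row.choice))
    return [scenarios[k] for k in sorted(scenarios)], records


def write_choice_table(
    path: str | Path,
    scenarios: list[ChoiceScenario],
    records: list[ChoiceRecord],
) -> None:
    """Write a choices table; prices in whole pounds (UK) or whole yen (JP)."""
    by_id = {s.scenario_id: s for s in scenarios}
    rows = []
    for rec in records:
        try:
            s = by_id[rec.scenario_id]
        except KeyError:
            raise ValueError(f"record references unknown scenario {rec.scenario_id}") from None
        currency = Currency.GBP if rec.country is Country.UK else Currency.JPY
        scale = 1_000 if currency is Currency.GBP else 150_000
        rows.append(
            {
                "participant_id": rec.participant_id,
                "country": rec.country.value,
                "scenario_id": s.scenario_id,
                "model_a": s.car_a.program.value,
                "price_a": round(s.car_a.price * scale),
                "model_b": s.car_b.program.value,
                "price_b": round(s.car_b.price * scale),
                "currency": currency.value,
                "choice": rec.choice,
            }
        )
    pd.DataFrame(rows, columns=_CHOICE_COLUMNS).to_csv(path, index=False)


def read_preference_table(path: str | Path) -> list[PreferenceResponse]:
    df = _load(path, _PREFERENCE_COLUMNS)
    out: list[PreferenceResponse] = []
    seen: set[tuple[str, Frame]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        country = _parse_enum(Country, row.country, "country", line)
        frame = _parse_enum(Frame, row.frame, "frame", line)
        choice = _parse_enum(PreferenceChoice, row.choice, "choice", line)
        key = (row.participant_id, frame)
        if key in seen:
            raise ParseError(
                f"duplicate response for participant {row.participant_id!r} "
                f"frame {frame.value}",
                line,
            )
        seen.add(key)
        out.append(PreferenceResponse(row.participant_id, country, frame, choice))
    return out


def write_preference_table(path: str | Path, responses: list[PreferenceResponse]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "country": r.country.value,
                "frame": r.frame.value,
                "choice": r.choice.value,
            }
            for r in responses
        ],
        columns=_PREFERENCE_COLUMNS,
    ).to_csv(path, index=False)


def read_likert_table(path: str | Path) -> list[LikertResponse]:
    df = _load(path, _LIKERT_COLUMNS)
    out: list[LikertResponse] = []
    seen: set[tuple[str, Condition]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        country = _parse_enum(Country, row.country, "country", line)
        condition = _parse_enum(Condition, row.condition, "condition", line)
        try:
            response = int(row.response)
            if not 1 <= response <= 7:
                raise ValueError
        except ValueError:
            raise ParseError(
                f"invalid response {row.response!r}; expected an integer in 1..7", line
            ) from None
        key = (row.participant_id, condition)
        if key in seen:
            raise ParseError(
                f"duplicate response for participant {row.participant_id!r} "
                f"condition {condition.value}",
                line,
            )
        seen.add(key)
        out.append(LikertResponse(row.participant_id, country, condition, response))
    return out


def write_likert_table(path: str | Path, responses: list[LikertResponse]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "country": r.country.value,
                "condition": r.condition.value,
                "response": r.response,
            }
            for r in responses
        ],
        columns=_LIKERT_COLUMNS,
    ).to_csv(path, index=False)


def choices_to_frame(
    scenarios: list[ChoiceScenario], records: list[ChoiceRecord]
) -> pd.DataFrame:
    """Join records with scenario attributes into the tidy frame the model fits.

    Columns: participant_id, scenario_id, program_a, price_a, program_b,
    price_b (prices in £k), choice.
    """
    by_id = {s.scenario_id: s for s in scenarios}
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "scenario_id": [r.scenario_id for r in records],
            "program_a": [by_id[r.scenario_id].car_a.program.value for r in records],
            "price_a": [by_id[r.scenario_id].car_a.price for r in records],
            "program_b": [by_id[r.scenario_id].car_b.program.value for r in records],
            "price_b": [by_id[r.scenario_id].car_b.price for r in records],
            "choice": [r.choice for r in records],
        }
    )
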