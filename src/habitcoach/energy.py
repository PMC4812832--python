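"""Energy expenditure and intake.

Calories burned follow the standard MET convention

    kcal = MET x body mass (kg) x duration (h)

with MET values taken from a small activity table (a synthetic excerpt in
the spirit of the compendium of physical activities). Calories consumed
come from a food table lookup, ``kcal_per_unit x quantity``, unless the
entry carries a direct calorie override (label calories on packaged food).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


class UnknownLabelError(KeyError):
    """Raised when an activity label or food id is not in its table."""


@dataclass(frozen=True)
class MetTable:
    """Map from activity label to MET value (multiple of resting metabolism)."""

    mets: dict[str, float]

    def __post_init__(self):
        for label, met in self.mets.items():
            if met <= 0:
                raise ValueError(f"MET for {label!r} must be > 0, got {met}")

    def __contains__(self, label: str) -> bool:
        return label in self.mets

    def __getitem__(self, label: str) -> float:
        try:
            return self.mets[label]
        except KeyError:
            raise UnknownLabelError(f"no MET value for activity label {label!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetTable":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls({r["label"]: float(r["met"]) for r in rows})

    @classmethod
    def default(cls) -> "MetTable":
        with resources.as_file(resources.files("habitcoach.data") / "met_table.csv") as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    name: str
    kcal_per_unit: float
    ingredients: frozenset[str]


@dataclass(frozen=True)
class FoodTable:
    """Food database fixture: per-unit calories and an ingredient token set."""

    items: dict[str, FoodItem] = field(default_factory=dict)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.items

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self.items[food_id]
        except KeyError:
            raise UnknownLabelError(f"unknown food_id {food_id!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoodTable":
        items: dict[str, FoodItem] = {}
        with open(path, newline="") as fh:
            for r in csv.DictReader(fh):
                ingredients = frozenset(
                    tok.strip() for tok in r["ingredients"].split(";") if tok.strip()
                )
                items[r["food_id"]] = FoodItem(
                    r["food_id"], r["name"], float(r["kcal_per_unit"]), ingredients
                )
        return cls(items)

    @classmethod
    def default(cls) -> "FoodTable":
        with resources.as_file(resources.files("habitcoach.data") / "food_table.csv") as p:
            return cls.from_csv(p)


def activity_kcal(
    label: str,
    duration_minutes: float,
    weight_kg: float,
    met_table: MetTable,
) -> float:
    """Gross calories burned for one activity bout.

    Linear in duration and body mass; resting expenditure is not subtracted.
    """
    if duration_minutes < 0:
        raise ValueError("duration_minutes must be >= 0")
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    met = met_table[label]
    return met * weight_kg * (duration_minutes / 60.0)


def mixed_kcal(
    constituents: list[tuple[str, float]],
    weight_kg: float,
    met_table: MetTable,
) -> float:
    """Duration-weighted calorie total for a mixed event.

    ``constituents`` is a list of (label, duration_minutes) pairs.
    """
    return sum(activity_kcal(lbl, dur, weight_kg, met_table) for lbl, dur in constituents)


def food_kcal(
    food_id: str | None,
    quantity: float,
    food_table: FoodTable,
    override_kcal: float | None = None,
) -> float:
    """Calories consumed for one food-log entry.

    A direct-entry override (calories read off a package label) bypasses the
    table entirely and is returned as-is.
    """
    if override_kcal is not None:
        if override_kcal < 0:
            raise ValueError("override_kcal must be >= 0")
        return float(override_kcal)
    if quantity < 0:
        raise ValueError("quantity must be >= 0")
    return food_table[food_id].kcal_per_unit * quantity
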