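"""Covariate codebook: the declarative description of the survey instrument.

A :class:`Codebook` lists every covariate that enters the risk-factor model,
its measurement kind, and (for categorical items) the ordered category list
whose first element is the reference level.  The codebook drives dummy
expansion: a k-category item becomes one *group* of k-1 indicator columns,
a continuous item a singleton group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

KINDS = ("continuous", "binary", "nominal", "ordinal")

# Frequency scale shared by most behaviour/diet items.
_FREQ = ("no", "occasional", "often", "always")


@dataclass(frozen=True)
class CodebookEntry:
    """One covariate: name, measurement kind, and ordered categories.

    For non-continuous entries the first category is the reference level and
    is omitted from the design matrix.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.categories:
                raise ValueError(f"continuous entry {self.name!r} has categories")
        else:
            if len(self.categories) < 2:
                raise ValueError(f"entry {self.name!r} needs >= 2 categories")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories in {self.name!r}")
        if self.kind == "binary" and len(self.categories) != 2:
            raise ValueError(f"binary entry {self.name!r} must have 2 categories")

    @property
    def n_dummies(self) -> int:
        """Number of design-matrix columns this covariate contributes."""
        if self.kind == "continuous":
            return 1
        return len(self.categories) - 1

    @property
    def reference(self) -> str | None:
        return self.categories[0] if self.categories else None


@dataclass(frozen=True)
class Codebook:
    entries: tuple[CodebookEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_columns(self) -> int:
        """Total design-matrix columns after dummy expansion."""
        return sum(e.n_dummies for e in self.entries)

    def __getitem__(self, name: str) -> CodebookEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> list[dict]:
        out = []
        for e in self.entries:
            d: dict = {"name": e.name, "kind": e.kind}
            if e.kind != "continuous":
                d["categories"] = list(e.categories)
            out.append(d)
        return out

    @classmethod
    def from_dict(cls, entries: Iterable[dict]) -> "Codebook":
        return cls(
            tuple(
                CodebookEntry(
                    name=d["name"],
                    kind=d["kind"],
                    categories=tuple(d.get("categories", ())),
                )
                for d in entries
            )
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_codebook() -> Codebook:
    """The default 31-covariate instrument: 4 continuous anthropometrics plus
    27 categorical questionnaire items, expanding to 72 design columns.

    Item wording is generic; the structure (counts of binary/ordinal items and
    their category numbers) mirrors a childhood lead-exposure lifestyle and
    residential-environment questionnaire.
    """
    cont = [CodebookEntry(n, "continuous") for n in (
        "height_cm",
        "weight_kg",
        "head_circumference_cm",
        "chest_circumference_cm",
    )]
    binaries = [CodebookEntry(n, "binary", ("no", "yes")) for n in (
        "ewaste_workshop_50m",      # e-waste piles/recycling workshops near house
        "parent_ewaste_worker",
        "drinking_water_treated",
        "house_recently_renovated",
        "residence_over_5_years",
        "pica_behavior",
    )]
    binaries.insert(0, CodebookEntry("sex", "binary", ("boy", "girl")))
    three_cat = [
        CodebookEntry("age_group", "ordinal", ("<3", "3-6", ">=6")),
        CodebookEntry("outdoor_play_hours", "ordinal", ("0-1", "1-3", ">=3")),
    ]
    freq_items = [CodebookEntry(n, "ordinal", _FREQ) for n in (
        "wash_hands_before_eating",
        "hand_to_mouth_activity",
        "eat_preserved_eggs",
        "eat_dairy_products",
        "eat_canned_food",
        "eat_bean_products",
        "eat_puffed_food",
        "eat_street_food",
        "mineral_supplement_use",
        "contact_ewaste",
        "play_near_ewaste_site",
        "nail_biting",
        "wash_fruit_before_eating",
        "share_utensils",
    )]
    other_four = [
        CodebookEntry("road_distance", "ordinal", ("<10m", "10-50m", "50-100m", ">100m")),
        CodebookEntry(
            "household_income", "ordinal", ("<1000", "1000-1500", "1500-2000", ">2000")
        ),
    ]
    five_six = [
        CodebookEntry(
            "family_cigarettes_per_day",
            "ordinal",
            ("none", "about2", "about10", "about20", "over20"),
        ),
        CodebookEntry(
            "mother_education",
            "ordinal",
            (
                "illiteracy",
                "primary",
                "junior_secondary",
                "vocational",
                "senior_secondary",
                "undergraduate",
            ),
        ),
    ]
    entries = tuple(cont + binaries + three_cat + freq_items + other_four + five_six)
    cb = Codebook(entries)
    assert len(cb) == 31 and cb.n_columns == 72
    return cb
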