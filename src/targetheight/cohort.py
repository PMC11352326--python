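"""Nuclear-family cohort containers and CSV input/output.

A cohort is a list of nuclear families, each with both parents and at
least one adult child.  The on-disk form is a flat CSV with one row per
person: ``family_id, person_id, role, sex, age_years, height_cm`` with
role in {father, mother, child} and sex in {M, F}.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .reference import Sex

__all__ = ["Role", "Member", "Family", "Cohort"]

#: Plausibility window for adult standing height, cm.
HEIGHT_RANGE = (100.0, 230.0)
#: Minimum age for inclusion as an adult height.
MIN_ADULT_AGE = 15.0


class Role(enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    CHILD = "child"

    @classmethod
    def parse(cls, value: "Role | str") -> "Role":
        if isinstance(value, Role):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(f"unknown role {value!r} (expected father/mother/child)") from None


@dataclass(frozen=True)
class Member:
    """One measured person: identity, sex, age at measurement, height (cm)."""

    person_id: str
    family_id: str
    role: Role
    sex: Sex
    age: Optional[float]   # None = age unknown (allowed only with assume_peak)
    height: float

    def __post_init__(self) -> None:
        lo, hi = HEIGHT_RANGE
        if not (lo < self.height < hi):
            raise ValueError(
                f"{self.person_id or 'member'}: height {self.height} cm outside "
                f"plausible adult range ({lo}, {hi})"
            )
        if self.age is not None and self.age < MIN_ADULT_AGE:
            raise ValueError(
                f"{self.person_id or 'member'}: age {self.age} < {MIN_ADULT_AGE}; "
                "only adult heights are modelled"
            )
        if self.role is Role.FATHER and self.sex is not Sex.MALE:
            raise ValueError(f"{self.person_id}: father must be male")
        if self.role is Role.MOTHER and self.sex is not Sex.FEMALE:
            raise ValueError(f"{self.person_id}: mother must be female")

    @classmethod
    def parent(
        cls, sex: "Sex | str", height: float, age: Optional[float] = None,
        person_id: str = "", family_id: str = "",
    ) -> "Member":
        """Convenience constructor for a clinical-query parent."""
        sex = Sex.parse(sex)
        role = Role.FATHER if sex is Sex.MALE else Role.MOTHER
        return cls(person_id=person_id, family_id=family_id, role=role,
                   sex=sex, age=age, height=float(height))


@dataclass(frozen=True)
class Family:
    father: Member
    mother: Member
    children: tuple[Member, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise ValueError(f"family {self.family_id!r} has no children")

    @property
    def family_id(self) -> str:
        return self.father.family_id

    def children_of_sex(self, sex: Sex) -> tuple[Member, ...]:
        return tuple(c for c in self.children if c.sex is sex)


@dataclass(frozen=True)
class Cohort:
    families: tuple[Family, ...]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("cohort has no families")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[Family]:
        return iter(self.families)

    @property
    def n_children(self) -> int:
        return sum(len(f.children) for f in self.families)

    def members(self) -> Iterator[Member]:
        for fam in self.families:
            yield fam.father
            yield fam.mother
            yield from fam.children

    # ---- CSV round trip -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        required = {"family_id", "person_id", "role", "sex", "age_years", "height_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns {sorted(missing)}")
        families = []
        for fid, group in df.groupby("family_id", sort=True):
            members: dict[Role, list[Member]] = {r: [] for r in Role}
            for _, row in group.iterrows():
                age = row["age_years"]
                member = Member(
                    person_id=str(row["person_id"]),
                    family_id=str(fid),
                    role=Role.parse(row["role"]),
                    sex=Sex.parse(row["sex"]),
                    age=None if pd.isna(age) else float(age),
                    height=float(row["height_cm"]),
                )
                members[member.role].append(member)
            if len(members[Role.FATHER]) != 1 or len(members[Role.MOTHER]) != 1:
                raise ValueError(
                    f"family {fid!r}: needs exactly one father and one mother, got "
                    f"{len(members[Role.FATHER])}/{len(members[Role.MOTHER])}"
                )
            families.append(
                Family(
                    father=members[Role.FATHER][0],
                    mother=members[Role.MOTHER][0],
                    children=tuple(members[Role.CHILD]),
                )
            )
        return cls(families=tuple(families))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": m.family_id,
                "person_id": m.person_id,
                "role": m.role.value,
                "sex": "M" if m.sex is Sex.MALE else "F",
                "age_years": m.age,
                "height_cm": m.height,
            }
            for m in self.members()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)
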