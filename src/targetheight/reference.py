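"""Reference-population parameters and growth-chart percentile tables.

Adult stature is modelled per sex as Normal(mean, sd), which is what the
standard clinical conversions between height, standard-deviation score
(SDS, z-score) and percentile assume.  The shipped default reference,
:data:`CDC_DERIVED`, carries per-sex means and SDs consistent with the
CDC 2000 adult (age-20) stature distribution: the female SD is fixed by
the convention that a 1.64-SDS band spans 10.6 cm, the male SD by an
11.7 cm band, the female mean is 163 cm (the female 50th percentile) and
the male mean places 163 cm at the male 3rd percentile.

A :class:`PercentileTable` holds the age-20 row of a growth chart (the
nine standard percentiles: 3, 5, 10, 25, 50, 75, 90, 95, 97) and supports
the male-vs-female analyses: the per-percentile sex difference profile and
the zero-intercept multiplicative sex factor (male ≈ 1.08 × female on the
CDC charts).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "Sex",
    "ReferencePopulation",
    "PercentileTable",
    "SexDifferenceProfile",
    "CDC_DERIVED",
    "STANDARD_PERCENTILES",
    "height_to_zscore",
    "zscore_to_height",
    "height_to_percentile",
    "percentile_to_height",
    "sds_interval_to_cm",
    "fit_multiplicative_factor",
    "sex_difference_profile",
    "read_reference_table",
    "load_reference_population",
    "packaged_growth_chart_path",
]

#: The nine percentiles printed on CDC stature-for-age charts, as fractions.
STANDARD_PERCENTILES: tuple[float, ...] = (
    0.03, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.97,
)


class Sex(enum.Enum):
    """Biological sex, as used by growth references (two values)."""

    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "Sex | str | int") -> "Sex":
        """Coerce common encodings: 'M'/'F', 'male'/'female', CDC 1/2."""
        if isinstance(value, Sex):
            return value
        if isinstance(value, (int, np.integer)):
            if int(value) == 1:
                return cls.MALE
            if int(value) == 2:
                return cls.FEMALE
            raise ValueError(f"unknown sex code {value!r} (CDC uses 1=male, 2=female)")
        text = str(value).strip().lower()
        if text in {"m", "male", "son", "boy", "1"}:
            return cls.MALE
        if text in {"f", "female", "daughter", "girl", "2"}:
            return cls.FEMALE
        raise ValueError(f"unknown sex {value!r}")


@dataclass(frozen=True)
class ReferencePopulation:
    """Per-sex adult mean and SD of height, in cm."""

    mean_male: float
    sd_male: float
    mean_female: float
    sd_female: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.sd_male > 0 and self.sd_female > 0):
            raise ValueError("reference SDs must be positive")
        for v in (self.mean_male, self.sd_male, self.mean_female, self.sd_female):
            if not math.isfinite(v):
                raise ValueError("reference parameters must be finite")

    def mean(self, sex: Sex) -> float:
        return self.mean_male if Sex.parse(sex) is Sex.MALE else self.mean_female

    def sd(self, sex: Sex) -> float:
        return self.sd_male if Sex.parse(sex) is Sex.MALE else self.sd_female

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_male": self.mean_male,
            "sd_male": self.sd_male,
            "mean_female": self.mean_female,
            "sd_female": self.sd_female,
        }


# Derived CDC-consistent adult reference (see module docstring).  The male
# mean follows from placing 163 cm at the male 3rd percentile:
#   mean_male = 163 - Phi^{-1}(0.03) * sd_male.
_Z03 = float(norm.ppf(0.03))
CDC_DERIVED = ReferencePopulation(
    mean_male=163.0 - _Z03 * (11.7 / 1.64),
    sd_male=11.7 / 1.64,
    mean_female=163.0,
    sd_female=10.6 / 1.64,
    label="cdc-derived",
)


def _check_height(height: float) -> float:
    h = float(height)
    if not math.isfinite(h):
        raise ValueError(f"height must be finite, got {height!r}")
    return h


def height_to_zscore(height: float, sex: Sex, ref: ReferencePopulation = CDC_DERIVED) -> float:
    """Standard-deviation score of ``height`` against the per-sex reference."""
    return (_check_height(height) - ref.mean(sex)) / ref.sd(sex)


def zscore_to_height(z: float, sex: Sex, ref: ReferencePopulation = CDC_DERIVED) -> float:
    """Inverse of :func:`height_to_zscore`."""
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z!r}")
    return ref.mean(sex) + z * ref.sd(sex)


def _check_fraction(p: float) -> float:
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError(f"percentile must be a fraction in (0, 1), got {p!r}")
    return p


def percentile_to_height(p: float, sex: Sex, ref: ReferencePopulation = CDC_DERIVED) -> float:
    """Height at percentile ``p`` (fraction in (0,1)) under the normal model."""
    return zscore_to_height(norm.ppf(_check_fraction(p)), sex, ref)


def height_to_percentile(height: float, sex: Sex, ref: ReferencePopulation = CDC_DERIVED) -> float:
    """Percentile (fraction) of ``height``; exact inverse of :func:`percentile_to_height`."""
    return float(norm.cdf(height_to_zscore(height, sex, ref)))


def sds_interval_to_cm(sds: float, sex: Sex, ref: ReferencePopulation = CDC_DERIVED) -> float:
    """Width in cm of an ``sds``-wide standard-deviation-score band for ``sex``.

    E.g. the classical ±1.64 SDS normal range spans 1.64 × sd_sex cm on
    each side of the target (10.6 cm for girls, 11.7 cm for boys under the
    shipped reference).
    """
    sds = float(sds)
    if sds < 0:
        raise ValueError("sds must be non-negative")
    return sds * ref.sd(sex)


@dataclass(frozen=True)
class PercentileTable:
    """Age-20 growth-chart row: per-percentile male and female heights (cm)."""

    percentiles: tuple[float, ...]
    height_male: tuple[float, ...]
    height_female: tuple[float, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        m = np.asarray(self.height_male, dtype=float)
        f = np.asarray(self.height_female, dtype=float)
        if not (len(p) == len(m) == len(f)):
            raise ValueError("percentile table columns must have equal length")
        if len(p) < 2:
            raise ValueError("percentile table needs at least two rows")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("percentiles must be fractions in (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing")
        for name, col in (("male", m), ("female", f)):
            if np.any(np.diff(col) <= 0):
                raise ValueError(f"{name} heights must be strictly increasing with percentile")

    def heights(self, sex: Sex) -> np.ndarray:
        col = self.height_male if Sex.parse(sex) is Sex.MALE else self.height_female
        return np.asarray(col, dtype=float)

    def height_at(self, p: float, sex: Sex) -> float:
        """Monotone piecewise-linear interpolation on the probit scale."""
        z = norm.ppf(_check_fraction(p))
        zs = norm.ppf(np.asarray(self.percentiles))
        return float(np.interp(z, zs, self.heights(sex)))

    def percentile_of(self, height: float, sex: Sex) -> float:
        zs = norm.ppf(np.asarray(self.percentiles))
        z = float(np.interp(_check_height(height), self.heights(sex), zs))
        return float(norm.cdf(z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "height_male": self.height_male,
                "height_female": self.height_female,
            }
        )


def fit_multiplicative_factor(
    pairs: "PercentileTable | Iterable[tuple[float, float]]",
) -> float:
    """Zero-intercept least-squares slope of male on female height.

    ``pairs`` is either a :class:`PercentileTable` or an iterable of
    ``(female_height, male_height)`` tuples matched by percentile.  The
    regression of male height m on female height f through the origin has
    the closed form k = Σ(m·f) / Σ(f²).  On the CDC age-20 chart this is
    the multiplicative sex-correction factor, ≈ 1.08.
    """
    if isinstance(pairs, PercentileTable):
        f = pairs.heights(Sex.FEMALE)
        m = pairs.heights(Sex.MALE)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("need at least two (female, male) height pairs")
        f, m = arr[:, 0], arr[:, 1]
    if np.any(f < 0) or np.any(m < 0):
        raise ValueError("heights must be non-negative")
    denom = float(np.dot(f, f))
    if denom == 0.0:
        raise ValueError("female heights are all zero; slope undefined")
    return float(np.dot(m, f) / denom)


@dataclass(frozen=True)
class SexDifferenceProfile:
    """Male-minus-female height difference at matched percentiles + linear fit."""

    female_height: tuple[float, ...]
    difference: tuple[float, ...]
    slope: float       # d(difference)/d(female height), dimensionless
    intercept: float   # cm
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"female_height": self.female_height, "difference": self.difference}
        )


def sex_difference_profile(table: PercentileTable) -> SexDifferenceProfile:
    """Per-percentile male−female differences and their regression on female height.

    On the CDC charts the difference grows linearly with height (12.2 cm at
    the 3rd percentile, 14.7 cm at the 97th), which is what motivates a
    multiplicative rather than additive sex correction.
    """
    f = table.heights(Sex.FEMALE)
    d = table.heights(Sex.MALE) - f
    slope, intercept = np.polyfit(f, d, 1)
    pred = slope * f + intercept
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0.0:
        # constant difference: the flat fit is exact up to rounding error
        r2 = 1.0 if ss_res < 1e-18 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return SexDifferenceProfile(
        female_height=tuple(f),
        difference=tuple(d),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


_CDC_PCT_COLS = {"P3": 0.03, "P5": 0.05, "P10": 0.10, "P25": 0.25,
                 "P50": 0.50, "P75": 0.75, "P90": 0.90, "P95": 0.95, "P97": 0.97}


def read_reference_table(path: str | Path) -> PercentileTable:
    """Read a growth-chart CSV into a :class:`PercentileTable`.

    Two dialects are accepted, detected from the header:

    * CDC ``statage`` dialect — columns ``Sex`` (1=male, 2=female),
      ``Agemos`` and percentile columns ``P3 … P97``; the oldest age
      present (240 months on CDC files, i.e. age 20, the final chart
      entry) is taken as adult height.
    * simple dialect — columns ``percentile`` (0–1 fraction or 0–100),
      ``height_male``, ``height_female``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}

    if "sex" in cols and "agemos" in cols:
        return _read_cdc_dialect(df, cols, path)
    if {"percentile", "height_male", "height_female"} <= set(cols):
        return _read_simple_dialect(df, cols, path)
    raise ValueError(
        f"{path}: unrecognised growth-chart header {list(df.columns)!r}; "
        "expected CDC statage columns (Sex, Agemos, P3..P97) or "
        "(percentile, height_male, height_female)"
    )


def _read_simple_dialect(df: pd.DataFrame, cols: dict, path: Path) -> PercentileTable:
    out = {}
    for key in ("percentile", "height_male", "height_female"):
        series = pd.to_numeric(df[cols[key]], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            # +2: one for the header, one for 0-based indexing
            raise ValueError(f"{path}: line {bad[0] + 2}: non-numeric value in column {key!r}")
        out[key] = series.to_numpy(dtype=float)
    p = out["percentile"]
    if np.any(p >= 1.0):  # 0-100 convention
        p = p / 100.0
    return PercentileTable(
        percentiles=tuple(p),
        height_male=tuple(out["height_male"]),
        height_female=tuple(out["height_female"]),
        provenance=str(path),
    )


def _read_cdc_dialect(df: pd.DataFrame, cols: dict, path: Path) -> PercentileTable:
    missing = [c for c in _CDC_PCT_COLS if c.lower() not in cols]
    if missing:
        raise ValueError(f"{path}: CDC dialect is missing percentile columns {missing}")
    df = df.copy()
    df["_sex"] = pd.to_numeric(df[cols["sex"]], errors="coerce")
    df["_age"] = pd.to_numeric(df[cols["agemos"]], errors="coerce")
    df = df.dropna(subset=["_sex", "_age"])
    oldest = df["_age"].max()
    rows = df[df["_age"] == oldest]
    heights: dict[Sex, list[float]] = {}
    for sex_code, sex in ((1, Sex.MALE), (2, Sex.FEMALE)):
        sel = rows[rows["_sex"] == sex_code]
        if len(sel) != 1:
            raise ValueError(
                f"{path}: expected exactly one row for sex={sex_code} at Agemos={oldest}, "
                f"found {len(sel)}"
            )
        row = sel.iloc[0]
        heights[sex] = [float(row[cols[c.lower()]]) for c in _CDC_PCT_COLS]
    return PercentileTable(
        percentiles=tuple(_CDC_PCT_COLS.values()),
        height_male=tuple(heights[Sex.MALE]),
        height_female=tuple(heights[Sex.FEMALE]),
        provenance=f"{path} (Agemos={oldest:g})",
    )


def load_reference_population(path: str | Path) -> ReferencePopulation:
    """Load a reference population from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping with mean/sd fields")
    try:
        return ReferencePopulation(
            mean_male=float(data["mean_male"]),
            sd_male=float(data["sd_male"]),
            mean_female=float(data["mean_female"]),
            sd_female=float(data["sd_female"]),
            label=str(data.get("label", path.stem)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing reference field {exc}") from exc


def packaged_growth_chart_path() -> Path:
    """Path of the packaged synthetic age-20 growth-chart fixture.

    The file is a synthetic stand-in for the CDC stature-for-age chart's
    final (240-month) row, constructed so that the female column follows
    the shipped normal reference and the male−female difference matches
    the published CDC anchors (12.2 cm at the 3rd percentile, 14.7 cm at
    the 97th, linear in height).
    """
    with resources.as_file(
        resources.files("targetheight.data") / "cdc_statage_age20_synthetic.csv"
    ) as p:
        return Path(p)
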