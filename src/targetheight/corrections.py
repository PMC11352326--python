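"""Age and sex corrections of measured adult heights.

Two transformations are composed before any mid-parental arithmetic:

1. **Age (shrinkage) correction** — standing height is lost from about age
   30 onward at a rate that increases with age.  Cumulative loss is
   modelled as quadratic in years past onset,
   ``shrinkage(a) = accel · (a − 30)²`` for ``a > 30``, i.e. a shrinkage
   *rate* that accelerates at a constant rate.  ``peak_height`` adds the
   loss back, recovering the height the person had as a young adult.  The
   default acceleration, 2.7/32² ≈ 0.00264 cm/y², is calibrated so that a
   parent at the reference cohort's mean age of 62 has shrunk by 2.7 cm —
   the mean intergenerational height difference observed when no age
   correction is applied.

2. **Sex correction** — places both sexes on a common scale so parents can
   be averaged.  Three variants:

   * ``additive``: female + c (male-equivalent cm); Tanner's classical
     c = 13 cm, or a cohort-specific constant such as 10.82 cm.
   * ``multiplicative``: female × k; k = 1.08 from the CDC age-20 charts
     (Galton's 1886 choice), or a cohort-specific 1.066.
   * ``zscore``: (height − mean_sex)/sd_sex against a
     :class:`~targetheight.reference.ReferencePopulation` (dimensionless).

   Every variant has an exact inverse (``from_common_scale``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .reference import CDC_DERIVED, ReferencePopulation, Sex

__all__ = [
    "AgeShrinkageModel",
    "SchemeVariant",
    "SexCorrectionScheme",
    "DEFAULT_SHRINKAGE",
    "SCHEME_PRESETS",
    "shrinkage",
    "peak_height",
    "get_scheme",
]

#: Calibrated default shrinkage acceleration (cm/year²): 2.7 cm lost by age 62.
DEFAULT_ACCELERATION = 2.7 / (62.0 - 30.0) ** 2


@dataclass(frozen=True)
class AgeShrinkageModel:
    """Quadratic cumulative height shrinkage beginning at ``onset_age``."""

    onset_age: float = 30.0
    accel_male: float = DEFAULT_ACCELERATION
    accel_female: float = DEFAULT_ACCELERATION

    def __post_init__(self) -> None:
        if self.onset_age <= 0:
            raise ValueError("onset_age must be positive")
        if self.accel_male < 0 or self.accel_female < 0:
            raise ValueError("shrinkage accelerations must be non-negative")

    def accel(self, sex: Sex) -> float:
        return self.accel_male if Sex.parse(sex) is Sex.MALE else self.accel_female

    def shrinkage(self, age: float, sex: Sex) -> float:
        """Cumulative height loss (cm) at ``age``; zero at or below onset."""
        age = float(age)
        if age < 0:
            raise ValueError("age must be non-negative")
        excess = age - self.onset_age
        if excess <= 0:
            return 0.0
        return self.accel(sex) * excess * excess

    def to_dict(self) -> dict:
        return {
            "onset_age": self.onset_age,
            "accel_male": self.accel_male,
            "accel_female": self.accel_female,
        }


DEFAULT_SHRINKAGE = AgeShrinkageModel()


def shrinkage(age: float, sex: Sex, model: AgeShrinkageModel = DEFAULT_SHRINKAGE) -> float:
    """Cumulative stature loss in cm at ``age`` for ``sex``."""
    return model.shrinkage(age, sex)


def peak_height(
    measured: float,
    age: float,
    sex: Sex,
    model: AgeShrinkageModel = DEFAULT_SHRINKAGE,
) -> float:
    """Age-corrected (young-adult peak) height: measured + shrinkage."""
    measured = float(measured)
    if not (measured > 0) or not math.isfinite(measured):
        raise ValueError("measured height must be positive and finite")
    return measured + model.shrinkage(age, sex)


class SchemeVariant(enum.Enum):
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    ZSCORE = "zscore"


@dataclass(frozen=True)
class SexCorrectionScheme:
    """One of the three sex-correction variants, with its parameters.

    ``additive`` and ``multiplicative`` map heights to male-equivalent cm
    (males pass through unchanged); ``zscore`` maps to dimensionless SDS
    and requires a reference population.  ``estimate_ref`` marks a zscore
    scheme whose reference is to be estimated from the cohort under
    analysis rather than shipped.
    """

    variant: SchemeVariant
    additive_constant: Optional[float] = None   # cm
    factor: Optional[float] = None              # dimensionless
    ref: Optional[ReferencePopulation] = None
    label: str = ""
    estimate_ref: bool = False

    def __post_init__(self) -> None:
        if self.variant is SchemeVariant.ADDITIVE and self.additive_constant is None:
            raise ValueError("additive scheme requires additive_constant")
        if self.variant is SchemeVariant.MULTIPLICATIVE:
            if self.factor is None or self.factor <= 0:
                raise ValueError("multiplicative scheme requires a positive factor")
        if (
            self.variant is SchemeVariant.ZSCORE
            and self.ref is None
            and not self.estimate_ref
        ):
            raise ValueError("zscore scheme requires a ReferencePopulation")

    @property
    def is_standardized(self) -> bool:
        """True when the common scale is dimensionless SDS rather than cm."""
        return self.variant is SchemeVariant.ZSCORE

    def with_ref(self, ref: ReferencePopulation) -> "SexCorrectionScheme":
        return SexCorrectionScheme(
            variant=self.variant,
            additive_constant=self.additive_constant,
            factor=self.factor,
            ref=ref,
            label=self.label,
            estimate_ref=False,
        )

    def _require_ref(self) -> ReferencePopulation:
        if self.ref is None:
            raise ValueError(
                f"scheme {self.label or self.variant.value!r} needs a reference "
                "population (sample-based zscore schemes must be given one, e.g. "
                "estimated from a cohort)"
            )
        return self.ref

    def to_common_scale(self, height: float, sex: Sex) -> float:
        """Map a measured (or peak) height onto the scheme's common scale."""
        height = float(height)
        if not (height > 0) or not math.isfinite(height):
            raise ValueError("height must be positive and finite")
        sex = Sex.parse(sex)
        if self.variant is SchemeVariant.ADDITIVE:
            return height + self.additive_constant if sex is Sex.FEMALE else height
        if self.variant is SchemeVariant.MULTIPLICATIVE:
            return height * self.factor if sex is Sex.FEMALE else height
        ref = self._require_ref()
        return (height - ref.mean(sex)) / ref.sd(sex)

    def from_common_scale(self, value: float, sex: Sex) -> float:
        """Exact inverse of :meth:`to_common_scale` for ``sex``."""
        value = float(value)
        if not math.isfinite(value):
            raise ValueError("common-scale value must be finite")
        sex = Sex.parse(sex)
        if self.variant is SchemeVariant.ADDITIVE:
            return value - self.additive_constant if sex is Sex.FEMALE else value
        if self.variant is SchemeVariant.MULTIPLICATIVE:
            return value / self.factor if sex is Sex.FEMALE else value
        ref = self._require_ref()
        return ref.mean(sex) + value * ref.sd(sex)

    def to_dict(self) -> dict:
        d: dict = {"variant": self.variant.value, "label": self.label}
        if self.additive_constant is not None:
            d["additive_constant"] = self.additive_constant
        if self.factor is not None:
            d["factor"] = self.factor
        if self.ref is not None:
            d["ref"] = self.ref.to_dict()
        return d


#: Named scheme presets.  The "-sample" constants (10.82 cm, 1.066) are the
#: published cohort-specific values; they are shipped, not recomputed.
SCHEME_PRESETS: dict[str, SexCorrectionScheme] = {
    "tanner13": SexCorrectionScheme(
        SchemeVariant.ADDITIVE, additive_constant=13.0, label="tanner13"
    ),
    "mult1.08": SexCorrectionScheme(
        SchemeVariant.MULTIPLICATIVE, factor=1.08, label="mult1.08"
    ),
    "zscore-cdc": SexCorrectionScheme(
        SchemeVariant.ZSCORE, ref=CDC_DERIVED, label="zscore-cdc"
    ),
    "add10.82-sample": SexCorrectionScheme(
        SchemeVariant.ADDITIVE, additive_constant=10.82, label="add10.82-sample"
    ),
    "mult1.066-sample": SexCorrectionScheme(
        SchemeVariant.MULTIPLICATIVE, factor=1.066, label="mult1.066-sample"
    ),
    "zscore-sample": SexCorrectionScheme(
        SchemeVariant.ZSCORE, estimate_ref=True, label="zscore-sample"
    ),
}


def get_scheme(name: str) -> SexCorrectionScheme:
    """Look up a scheme preset by name."""
    try:
        return SCHEME_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme preset {name!r}; available: {sorted(SCHEME_PRESETS)}"
        ) from None
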