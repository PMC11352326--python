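"""Clinical target-height prediction and normal-range assessment.

The corrected target-height algorithm, for two measured parents and the
sex of the child:

1. add back age-related shrinkage to each parent (``peak_height``);
2. map both peak heights onto a common scale with a sex-correction
   scheme;
3. average them (mid-parental value);
4. apply the regression-to-the-mean map on the standardized scale,
   ``z_target = slope · z_midparent + intercept`` with the fitted default
   (0.79, −0.077) — for cm-scale schemes the male-equivalent midparent is
   standardized against the male reference first and de-standardized
   after;
5. transform the corrected common-scale value back to the child's sex.

The resulting target height comes with the probability model of sibling
scatter: adult children are normally distributed around the family target
with an SD of about 4.7 cm (sons) / 4.4 cm (daughters) pooled over
families, so the probability that a child's projected adult height falls
a given distance from the target is a normal tail probability.  That
probability replaces, and is reported alongside, the classical fixed
cutoffs (Tanner's ±10 cm for boys / ±9 cm for girls, and ±1.64 SDS).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.stats import norm

from .cohort import Member
from .corrections import (
    DEFAULT_SHRINKAGE,
    AgeShrinkageModel,
    SexCorrectionScheme,
    get_scheme,
    peak_height,
)
from .reference import CDC_DERIVED, ReferencePopulation, Sex

__all__ = [
    "RegressionToMeanParams",
    "ResidualModel",
    "CutoffPolicy",
    "TargetPrediction",
    "Assessment",
    "DEFAULT_RTM",
    "RESIDUALS_WITHIN_FAMILY",
    "RESIDUALS_POOLED",
    "DEFAULT_CUTOFFS",
    "mid_parental",
    "tanner_target",
    "corrected_target",
    "deviation_probability",
    "assess_child",
]


@dataclass(frozen=True)
class RegressionToMeanParams:
    """Standardized-scale linear map from mid-parental z to child z."""

    slope: float = 0.79
    intercept: float = -0.077

    def __post_init__(self) -> None:
        if not (0 < self.slope <= 1.5):
            raise ValueError("rtm slope out of plausible range")

    def apply(self, z_midparent: float) -> float:
        return self.slope * z_midparent + self.intercept

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept}


DEFAULT_RTM = RegressionToMeanParams()


class ResidualBasis(enum.Enum):
    WITHIN_FAMILY = "within_family"
    POOLED = "pooled"


@dataclass(frozen=True)
class ResidualModel:
    """Per-sex SD (cm) of adult children's heights around the family target."""

    sd_son: float
    sd_daughter: float
    basis: ResidualBasis

    def __post_init__(self) -> None:
        if self.sd_son <= 0 or self.sd_daughter <= 0:
            raise ValueError("residual SDs must be positive")

    def sd(self, child_sex: Sex) -> float:
        return self.sd_son if Sex.parse(child_sex) is Sex.MALE else self.sd_daughter

    def to_dict(self) -> dict:
        return {"sd_son": self.sd_son, "sd_daughter": self.sd_daughter,
                "basis": self.basis.value}


#: Mean within-family residual SDs (averaged over families).
RESIDUALS_WITHIN_FAMILY = ResidualModel(4.5, 4.2, ResidualBasis.WITHIN_FAMILY)
#: Residual SDs pooling all children from all families (the clinical default:
#: a child in the clinic is compared against all-family variability).
RESIDUALS_POOLED = ResidualModel(4.7, 4.4, ResidualBasis.POOLED)


@dataclass(frozen=True)
class CutoffPolicy:
    """Classical fixed normal-range cutoffs, for comparison."""

    tanner_range_son: float = 10.0      # cm
    tanner_range_daughter: float = 9.0  # cm
    sds_range: float = 1.64             # dimensionless

    def __post_init__(self) -> None:
        if min(self.tanner_range_son, self.tanner_range_daughter, self.sds_range) <= 0:
            raise ValueError("cutoffs must be positive")

    def tanner_range(self, child_sex: Sex) -> float:
        return (self.tanner_range_son if Sex.parse(child_sex) is Sex.MALE
                else self.tanner_range_daughter)


DEFAULT_CUTOFFS = CutoffPolicy()


@dataclass(frozen=True)
class TargetPrediction:
    """A corrected target height with the method metadata that produced it."""

    target_height: float           # cm, child-sex scale
    target_percentile: float       # fraction in (0, 1)
    child_sex: Sex
    common_scale_midparent: float  # on the scheme's common scale
    midparent_z: float             # standardized midparent
    target_z: float                # standardized target (after rtm)
    scheme: SexCorrectionScheme
    shrinkage: AgeShrinkageModel
    rtm: RegressionToMeanParams
    ref: ReferencePopulation
    parent_peaks: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "target_height_cm": round(self.target_height, 1),
            "target_percentile": round(self.target_percentile * 100, 1),
            "child_sex": self.child_sex.value,
            "midparent_common_scale": self.common_scale_midparent,
            "midparent_z": self.midparent_z,
            "target_z": self.target_z,
            "father_peak_cm": self.parent_peaks[0],
            "mother_peak_cm": self.parent_peaks[1],
            "method": {
                "scheme": self.scheme.to_dict(),
                "shrinkage": self.shrinkage.to_dict(),
                "regression_to_mean": self.rtm.to_dict(),
                "reference": self.ref.to_dict(),
            },
        }


def mid_parental(father_common: float, mother_common: float) -> float:
    """Mid-parental value: arithmetic mean of two common-scale heights."""
    for v in (father_common, mother_common):
        if not math.isfinite(v):
            raise ValueError("common-scale parental values must be finite")
    return (float(father_common) + float(mother_common)) / 2.0


def tanner_target(father: float, mother: float, child_sex: Sex) -> float:
    """Classical Tanner target: (father + mother)/2 ± 6.5 cm by child sex.

    Algebraically identical to adding 13 cm to the mother, averaging on
    the male-equivalent scale, and transforming back to the child's sex.
    """
    if father <= 0 or mother <= 0:
        raise ValueError("parental heights must be positive")
    offset = 6.5 if Sex.parse(child_sex) is Sex.MALE else -6.5
    return (float(father) + float(mother)) / 2.0 + offset


def _peak(parent: Member, model: AgeShrinkageModel, assume_peak: bool) -> float:
    if parent.age is None:
        if not assume_peak:
            raise ValueError(
                f"parent {parent.person_id or parent.role.value!r} has no age; "
                "pass assume_peak=True to skip the shrinkage correction explicitly "
                "(silently skipping it biases the target low)"
            )
        return parent.height
    return peak_height(parent.height, parent.age, parent.sex, model)


def corrected_target(
    father: Member,
    mother: Member,
    child_sex: Sex,
    shrinkage: AgeShrinkageModel = DEFAULT_SHRINKAGE,
    scheme: "SexCorrectionScheme | str" = "zscore-cdc",
    rtm: RegressionToMeanParams = DEFAULT_RTM,
    ref: ReferencePopulation = CDC_DERIVED,
    assume_peak: bool = False,
) -> TargetPrediction:
    """Corrected target height for a child of the given parents.

    Parameters
    ----------
    father, mother
        Measured parents (sex, age in years, height in cm).  Ages may be
        omitted only with ``assume_peak=True``.
    child_sex
        Sex of the child whose target is computed.
    shrinkage, scheme, rtm, ref
        Age-correction model, sex-correction scheme (object or preset
        name), regression-to-the-mean coefficients, and the reference
        population used for standardization and percentile conversion.

    Returns
    -------
    TargetPrediction
        Target height (cm) and percentile for the child's sex, plus the
        intermediate values and full method metadata.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    child_sex = Sex.parse(child_sex)
    if father.sex is not Sex.MALE or mother.sex is not Sex.FEMALE:
        raise ValueError("father must be male and mother female")

    father_peak = _peak(father, shrinkage, assume_peak)
    mother_peak = _peak(mother, shrinkage, assume_peak)

    mp = mid_parental(
        scheme.to_common_scale(father_peak, Sex.MALE),
        scheme.to_common_scale(mother_peak, Sex.FEMALE),
    )

    if scheme.is_standardized:
        z_mp = mp
        z_target = rtm.apply(z_mp)
        common_target = z_target
    else:
        # cm common scale is male-equivalent: standardize against the male
        # reference, regress to the mean, de-standardize.
        z_mp = (mp - ref.mean_male) / ref.sd_male
        z_target = rtm.apply(z_mp)
        common_target = ref.mean_male + z_target * ref.sd_male

    target = scheme.from_common_scale(common_target, child_sex)
    pct = float(norm.cdf((target - ref.mean(child_sex)) / ref.sd(child_sex)))
    return TargetPrediction(
        target_height=target,
        target_percentile=pct,
        child_sex=child_sex,
        common_scale_midparent=mp,
        midparent_z=z_mp,
        target_z=z_target,
        scheme=scheme,
        shrinkage=shrinkage,
        rtm=rtm,
        ref=ref,
        parent_peaks=(father_peak, mother_peak),
    )


def deviation_probability(
    deviation: float,
    child_sex: Sex,
    residual: ResidualModel = RESIDUALS_POOLED,
) -> float:
    """One-sided tail probability of a signed deviation from the target.

    With D ~ Normal(0, sd_childsex), returns P(D ≤ deviation) for a
    negative deviation (child shorter than target) and P(D ≥ deviation)
    for a positive one; 0.5 at zero.  The two-sided probability is exactly
    twice this value.
    """
    deviation = float(deviation)
    if not math.isfinite(deviation):
        raise ValueError("deviation must be finite")
    sd = residual.sd(child_sex)
    return float(norm.sf(abs(deviation) / sd))


@dataclass(frozen=True)
class Assessment:
    """Normal-range assessment of a projected height against its target."""

    projected_height: float
    target_height: float
    deviation: float              # projected − target, cm
    probability: float            # one-sided tail
    probability_two_sided: float
    inside_tanner: bool
    tanner_range: float           # cm
    inside_sds: bool
    sds_range_cm: float           # cm equivalent of the SDS band
    child_sex: Sex
    residual: ResidualModel

    def to_dict(self) -> dict:
        return {
            "projected_height_cm": self.projected_height,
            "target_height_cm": round(self.target_height, 1),
            "deviation_cm": round(self.deviation, 1),
            "probability_percent": round(self.probability * 100),
            "probability_one_sided": self.probability,
            "probability_two_sided": self.probability_two_sided,
            "tanner_verdict": "inside" if self.inside_tanner else "outside",
            "tanner_range_cm": self.tanner_range,
            "sds_verdict": "inside" if self.inside_sds else "outside",
            "sds_range_cm": round(self.sds_range_cm, 1),
            "residual_model": self.residual.to_dict(),
        }


def assess_child(
    projected_height: float,
    prediction: TargetPrediction,
    residual: ResidualModel = RESIDUALS_POOLED,
    cutoffs: CutoffPolicy = DEFAULT_CUTOFFS,
    ref: Optional[ReferencePopulation] = None,
) -> Assessment:
    """Compare a child's projected adult height with the corrected target.

    Reports the signed deviation, the probability that a deviation at
    least that large arises from normal sibling variation, and the
    verdicts of the classical fixed cutoffs (Tanner cm band, ±1.64 SDS
    band) for comparison.
    """
    ref = ref if ref is not None else prediction.ref
    child_sex = prediction.child_sex
    deviation = float(projected_height) - prediction.target_height
    p_one = deviation_probability(deviation, child_sex, residual)
    tanner_rng = cutoffs.tanner_range(child_sex)
    sds_cm = cutoffs.sds_range * ref.sd(child_sex)
    return Assessment(
        projected_height=float(projected_height),
        target_height=prediction.target_height,
        deviation=deviation,
        probability=p_one,
        probability_two_sided=min(1.0, 2.0 * p_one),
        inside_tanner=abs(deviation) <= tanner_rng,
        tanner_range=tanner_rng,
        inside_sds=abs(deviation) <= sds_cm,
        sds_range_cm=sds_cm,
        child_sex=child_sex,
        residual=residual,
    )
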