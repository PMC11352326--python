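"""Cohort-level evaluation of target-height estimators.

The central object is :class:`MidparentModel`, an OLS regression of each
adult child's common-scale height on the family's mid-parental value
(one observation per child), after optional age correction and one of
the sex-correction schemes.  Its :meth:`~MidparentModel.fit` returns a
:class:`MidparentResults` carrying the slope — which in the mid-parental
design is the narrow-sense heritability estimate — the intercept, R²,
standard errors, and the systematic error (mean child-minus-midparent
difference, the prediction bias of the scheme).

Around it:

* :func:`scheme_comparison_table` — fits every combination of age
  correction on/off and sex-correction scheme and tabulates the results;
* :func:`within_family_residuals` — the distribution of siblings' adult
  heights around their family's corrected target, per sex, both within
  families and pooled;
* :func:`family_level_rtm` — the family-mean view of regression to the
  mean: mean child height minus midparent against midparent;
* :func:`residual_spread_vs_midparent` — tests whether taller families
  scatter more (heteroscedasticity of the residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, Family, Member
from .corrections import (
    DEFAULT_SHRINKAGE,
    AgeShrinkageModel,
    SexCorrectionScheme,
    get_scheme,
    peak_height,
)
from .prediction import (
    DEFAULT_RTM,
    RegressionToMeanParams,
    corrected_target,
    mid_parental,
)
from .reference import CDC_DERIVED, ReferencePopulation, Sex

__all__ = [
    "MidparentModel",
    "MidparentResults",
    "estimate_reference_from_cohort",
    "scheme_comparison_table",
    "within_family_residuals",
    "WithinFamilyResiduals",
    "family_level_rtm",
    "FamilyRegressionToMean",
    "residual_spread_vs_midparent",
    "TABLE_ROW_ORDER",
]

#: (age_corrected, scheme preset) combinations in standard reporting order.
TABLE_ROW_ORDER: tuple[tuple[bool, str], ...] = (
    (False, "tanner13"),
    (True, "tanner13"),
    (True, "mult1.08"),
    (True, "zscore-cdc"),
    (True, "add10.82-sample"),
    (True, "mult1.066-sample"),
    (True, "zscore-sample"),
)


def estimate_reference_from_cohort(
    cohort: Cohort,
    shrinkage: Optional[AgeShrinkageModel] = DEFAULT_SHRINKAGE,
    label: str = "sample",
) -> ReferencePopulation:
    """Per-sex mean/SD of (age-corrected) heights of all cohort members."""
    heights: dict[Sex, list[float]] = {Sex.MALE: [], Sex.FEMALE: []}
    for m in cohort.members():
        h = m.height
        if shrinkage is not None and m.age is not None:
            h = peak_height(h, m.age, m.sex, shrinkage)
        heights[m.sex].append(h)
    male = np.asarray(heights[Sex.MALE])
    female = np.asarray(heights[Sex.FEMALE])
    if len(male) < 2 or len(female) < 2:
        raise ValueError("need at least two members of each sex to estimate a reference")
    return ReferencePopulation(
        mean_male=float(male.mean()),
        sd_male=float(male.std(ddof=1)),
        mean_female=float(female.mean()),
        sd_female=float(female.std(ddof=1)),
        label=label,
    )


def _resolve_scheme(
    scheme: "SexCorrectionScheme | str",
    cohort: Cohort,
    shrinkage: Optional[AgeShrinkageModel],
) -> SexCorrectionScheme:
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if scheme.estimate_ref:
        scheme = scheme.with_ref(estimate_reference_from_cohort(cohort, shrinkage))
    return scheme


class MidparentModel:
    """Offspring-on-midparent regression model for a family cohort.

    Parameters
    ----------
    cohort
        Families with both parents and ≥1 adult child.
    scheme
        Sex-correction scheme (object or preset name) placing all heights
        on a common scale before regression.
    shrinkage
        Age-correction model applied to every member, or ``None`` to skip
        age correction entirely (the classical, biased analysis).
    assume_peak
        Treat members without an age as already at peak height.  Off by
        default because silently skipping the correction biases results.
    """

    def __init__(
        self,
        cohort: Cohort,
        scheme: "SexCorrectionScheme | str" = "mult1.08",
        shrinkage: Optional[AgeShrinkageModel] = DEFAULT_SHRINKAGE,
        assume_peak: bool = False,
    ) -> None:
        self.cohort = cohort
        self.shrinkage = shrinkage
        self.scheme = _resolve_scheme(scheme, cohort, shrinkage)
        self.assume_peak = assume_peak
        self.midparent, self.child_common, self._child_index = self._build_arrays()

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "MidparentModel":
        return cls(Cohort.from_csv(path), **kwargs)

    # ------------------------------------------------------------------

    def _corrected(self, member: Member) -> float:
        h = member.height
        if self.shrinkage is not None:
            if member.age is None:
                if not self.assume_peak:
                    raise ValueError(
                        f"{member.person_id!r} has no age; pass assume_peak=True "
                        "or shrinkage=None"
                    )
            else:
                h = peak_height(h, member.age, member.sex, self.shrinkage)
        return h

    def family_midparent(self, family: Family) -> float:
        """Common-scale mid-parental value for one family."""
        return mid_parental(
            self.scheme.to_common_scale(self._corrected(family.father), Sex.MALE),
            self.scheme.to_common_scale(self._corrected(family.mother), Sex.FEMALE),
        )

    def _build_arrays(self):
        mp, child, index = [], [], []
        for fam in self.cohort:
            fam_mp = self.family_midparent(fam)
            for c in fam.children:
                mp.append(fam_mp)
                child.append(self.scheme.to_common_scale(self._corrected(c), c.sex))
                index.append((fam.family_id, c.person_id))
        return np.asarray(mp), np.asarray(child), index

    def fit(self) -> "MidparentResults":
        """Ordinary least squares of child common-scale height on midparent."""
        x, y = self.midparent, self.child_common
        if len(self.cohort) < 2:
            raise ValueError("need at least two families to regress")
        if np.ptp(x) == 0:
            raise ValueError("midparent values have zero variance; slope undefined")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        return MidparentResults(model=self, _ols=ols)


@dataclass
class MidparentResults:
    """Fitted offspring-on-midparent regression.

    Attributes
    ----------
    slope, intercept
        OLS coefficients; ``slope`` doubles as the heritability estimate.
    rsquared
        Fraction of children's height variance explained by midparent.
    systematic_error
        Mean(child − midparent) on the common scale: cm for additive and
        multiplicative schemes, standardized units for z-score schemes.
    """

    model: MidparentModel
    _ols: "sm.regression.linear_model.RegressionResultsWrapper"

    # -- estimates ------------------------------------------------------

    @property
    def intercept(self) -> float:
        return float(self._ols.params[0])

    @property
    def slope(self) -> float:
        return float(self._ols.params[1])

    @property
    def heritability(self) -> float:
        """Midparent-offspring regression slope, the heritability estimate."""
        return self.slope

    @property
    def bse(self) -> tuple[float, float]:
        """Standard errors of (intercept, slope)."""
        return (float(self._ols.bse[0]), float(self._ols.bse[1]))

    @property
    def slope_se(self) -> float:
        return self.bse[1]

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def systematic_error(self) -> float:
        return float(np.mean(self.model.child_common - self.model.midparent))

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    @property
    def units(self) -> str:
        return "SD" if self.model.scheme.is_standardized else "cm"

    @property
    def scheme_label(self) -> str:
        return self.model.scheme.label or self.model.scheme.variant.value

    @property
    def age_corrected(self) -> bool:
        return self.model.shrinkage is not None

    def as_rtm_params(self) -> RegressionToMeanParams:
        """The fitted line as regression-to-the-mean coefficients.

        Only meaningful for standardized (z-score) schemes, where slope
        and intercept are already on the standardized scale.
        """
        if not self.model.scheme.is_standardized:
            raise ValueError(
                "fitted cm-scale coefficients are not standardized rtm parameters; "
                "fit a zscore scheme instead"
            )
        return RegressionToMeanParams(slope=self.slope, intercept=self.intercept)

    # -- presentation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_label,
            "age_corrected": self.age_corrected,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.rsquared,
            "heritability": self.heritability,
            "systematic_error": self.systematic_error,
            "units": self.units,
            "n_children": self.nobs,
        }

    def summary(self) -> str:
        se_i, se_s = self.bse
        lines = [
            "Offspring-on-midparent regression",
            "=" * 49,
            f"scheme:            {self.scheme_label}"
            f" ({'age-corrected' if self.age_corrected else 'no age correction'})",
            f"families:          {len(self.model.cohort)}",
            f"children (n):      {self.nobs}",
            f"common scale:      {self.units}",
            "-" * 49,
            f"slope (h^2):       {self.slope:8.4f}  (SE {se_s:.4f})",
            f"intercept:         {self.intercept:8.4f}  (SE {se_i:.4f})",
            f"R-squared:         {self.rsquared:8.4f}",
            f"heritability:      {self.heritability * 100:7.1f}%",
            f"systematic error:  {self.systematic_error:8.4f} {self.units}",
            "=" * 49,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of child vs midparent common-scale heights with the fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.midparent, self.model.child_common
        ax.scatter(x, y, s=12, alpha=0.6, label="children")
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.intercept + self.slope * grid, color="crimson",
                label=f"y = {self.slope:.2f}x + {self.intercept:.2f}")
        ax.set_xlabel(f"mid-parental height ({self.units})")
        ax.set_ylabel(f"child height ({self.units})")
        ax.legend()
        return ax


def scheme_comparison_table(
    cohort: Cohort,
    schemes: Optional[Sequence[tuple[bool, str]]] = None,
    shrinkage: AgeShrinkageModel = DEFAULT_SHRINKAGE,
) -> pd.DataFrame:
    """Fit every (age correction, scheme) combination and tabulate.

    ``schemes`` is a sequence of (age_corrected, preset-name) pairs;
    default is the standard seven-row layout (uncorrected Tanner, then
    the six age-corrected schemes).
    """
    rows = []
    for age_on, name in (schemes if schemes is not None else TABLE_ROW_ORDER):
        res = MidparentModel(
            cohort, scheme=name, shrinkage=shrinkage if age_on else None
        ).fit()
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WithinFamilyResiduals:
    """Distribution of children's heights around the family target, per sex."""

    family_sds: dict[Sex, dict[str, float]]   # sex -> family_id -> SD (cm)
    mean_within: dict[Sex, float]             # mean of family SDs
    sd_within: dict[Sex, float]               # spread of family SDs
    pooled_sd: dict[Sex, float]               # SD pooling all children
    n_children: dict[Sex, int]
    residuals: dict[Sex, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def sexed(d):
            return {"sons": d[Sex.MALE], "daughters": d[Sex.FEMALE]}

        return {
            "within_family_mean_sd_cm": sexed(self.mean_within),
            "within_family_sd_of_sds_cm": sexed(self.sd_within),
            "pooled_sd_cm": sexed(self.pooled_sd),
            "n_children": sexed(self.n_children),
        }


def _family_residuals(
    family: Family,
    scheme: SexCorrectionScheme,
    shrinkage: Optional[AgeShrinkageModel],
    rtm: Optional[RegressionToMeanParams],
    ref: ReferencePopulation,
    assume_peak: bool,
) -> dict[Sex, np.ndarray]:
    """Children's residuals (cm, own-sex scale) around the family target."""
    shrink = shrinkage if shrinkage is not None else AgeShrinkageModel(
        accel_male=0.0, accel_female=0.0
    )
    out: dict[Sex, np.ndarray] = {}
    for sex in Sex:
        kids = family.children_of_sex(sex)
        if not kids:
            out[sex] = np.empty(0)
            continue
        if rtm is not None:
            target = corrected_target(
                family.father, family.mother, sex,
                shrinkage=shrink, scheme=scheme, rtm=rtm, ref=ref,
                assume_peak=assume_peak,
            ).target_height
        else:
            # raw midparent residuals (sensitivity analysis): no rtm pull
            mp = mid_parental(
                scheme.to_common_scale(
                    peak_height(family.father.height, family.father.age or 0, Sex.MALE, shrink)
                    if family.father.age is not None else family.father.height,
                    Sex.MALE,
                ),
                scheme.to_common_scale(
                    peak_height(family.mother.height, family.mother.age or 0, Sex.FEMALE, shrink)
                    if family.mother.age is not None else family.mother.height,
                    Sex.FEMALE,
                ),
            )
            target = scheme.from_common_scale(mp, sex)
        heights = []
        for c in kids:
            h = c.height
            if shrinkage is not None and c.age is not None:
                h = peak_height(h, c.age, c.sex, shrinkage)
            heights.append(h)
        out[sex] = np.asarray(heights) - target
    return out


def within_family_residuals(
    cohort: Cohort,
    scheme: "SexCorrectionScheme | str" = "mult1.08",
    shrinkage: Optional[AgeShrinkageModel] = DEFAULT_SHRINKAGE,
    rtm: Optional[RegressionToMeanParams] = DEFAULT_RTM,
    ref: ReferencePopulation = CDC_DERIVED,
    assume_peak: bool = False,
) -> WithinFamilyResiduals:
    """Per-sex scatter of adult children around their family target height.

    For each family and sex, children's (age-corrected) heights are
    compared with the family's corrected target on the child's own sex
    scale.  Families contribute a within-family SD for a sex only with
    ≥2 children of that sex.  Pass ``rtm=None`` to measure residuals
    around the raw (un-regressed) midparent instead — the sensitivity
    analysis for the regression-to-the-mean step.
    """
    scheme = _resolve_scheme(scheme, cohort, shrinkage)
    fam_sds: dict[Sex, dict[str, float]] = {s: {} for s in Sex}
    all_res: dict[Sex, list[np.ndarray]] = {s: [] for s in Sex}
    for fam in cohort:
        res = _family_residuals(fam, scheme, shrinkage, rtm, ref, assume_peak)
        for sex in Sex:
            if res[sex].size:
                all_res[sex].append(res[sex])
            if res[sex].size >= 2:
                fam_sds[sex][fam.family_id] = float(res[sex].std(ddof=1))

    mean_within, sd_within, pooled, counts, residuals = {}, {}, {}, {}, {}
    for sex in Sex:
        sds = np.asarray(list(fam_sds[sex].values()))
        mean_within[sex] = float(sds.mean()) if sds.size else float("nan")
        sd_within[sex] = float(sds.std(ddof=1)) if sds.size >= 2 else float("nan")
        pooled_res = (
            np.concatenate(all_res[sex]) if all_res[sex] else np.empty(0)
        )
        residuals[sex] = pooled_res
        counts[sex] = int(pooled_res.size)
        pooled[sex] = (
            float(pooled_res.std(ddof=1)) if pooled_res.size >= 2 else float("nan")
        )
    return WithinFamilyResiduals(
        family_sds=fam_sds,
        mean_within=mean_within,
        sd_within=sd_within,
        pooled_sd=pooled,
        n_children=counts,
        residuals=residuals,
    )


@dataclass(frozen=True)
class FamilyRegressionToMean:
    """Family-level regression to the mean: child-mean − midparent vs midparent."""

    frame: pd.DataFrame   # family_id, midparent, mean_child_diff
    r: float
    p_value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.frame["midparent"], self.frame["mean_child_diff"], s=20)
        if self.defined:
            b, a = np.polyfit(self.frame["midparent"], self.frame["mean_child_diff"], 1)
            grid = np.linspace(self.frame["midparent"].min(), self.frame["midparent"].max(), 20)
            ax.plot(grid, a + b * grid, color="crimson",
                    label=f"r = {self.r:.2f} (p = {self.p_value:.2g})")
            ax.legend()
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel("mid-parental height (common scale)")
        ax.set_ylabel("mean child − midparent")
        return ax


def family_level_rtm(
    cohort: Cohort,
    scheme: "SexCorrectionScheme | str" = "mult1.08",
    shrinkage: Optional[AgeShrinkageModel] = DEFAULT_SHRINKAGE,
    assume_peak: bool = False,
) -> FamilyRegressionToMean:
    """Correlation between family midparent and mean child-minus-midparent.

    A negative Pearson r is the family-level signature of regression to
    the mean: tall families' children fall short of their midparent and
    short families' children exceed it.  The p-value is the two-sided
    t-test with n−2 degrees of freedom.
    """
    if len(cohort) < 3:
        raise ValueError("need at least three families for a correlation")
    model = MidparentModel(cohort, scheme=scheme, shrinkage=shrinkage,
                           assume_peak=assume_peak)
    rows = []
    for fam in cohort:
        mp = model.family_midparent(fam)
        kids = [
            model.scheme.to_common_scale(model._corrected(c), c.sex)
            for c in fam.children
        ]
        rows.append(
            {"family_id": fam.family_id, "midparent": mp,
             "mean_child_diff": float(np.mean(kids)) - mp}
        )
    frame = pd.DataFrame(rows)
    # constant differences (e.g. a noise-free slope-1 cohort leaves only
    # rounding error) make the correlation undefined
    if frame["midparent"].std() == 0 or frame["mean_child_diff"].std() < 1e-12:
        return FamilyRegressionToMean(frame=frame, r=float("nan"), p_value=float("nan"))
    r, p = stats.pearsonr(frame["midparent"], frame["mean_child_diff"])
    return FamilyRegressionToMean(frame=frame, r=float(r), p_value=float(p))


def residual_spread_vs_midparent(
    cohort: Cohort,
    scheme: "SexCorrectionScheme | str" = "mult1.08",
    shrinkage: Optional[AgeShrinkageModel] = DEFAULT_SHRINKAGE,
    rtm: RegressionToMeanParams = DEFAULT_RTM,
    ref: ReferencePopulation = CDC_DERIVED,
    assume_peak: bool = False,
) -> FamilyRegressionToMean:
    """Correlation between family midparent height and family residual SD.

    Tests whether taller families show wider scatter of children around
    the target (heteroscedasticity).  Families need ≥2 children (any mix
    of sexes; residuals are taken on each child's own sex scale) to
    contribute an SD.
    """
    if len(cohort) < 3:
        raise ValueError("need at least three families for a correlation")
    scheme_obj = _resolve_scheme(scheme, cohort, shrinkage)
    model = MidparentModel(cohort, scheme=scheme_obj, shrinkage=shrinkage,
                           assume_peak=assume_peak)
    rows = []
    for fam in cohort:
        res = _family_residuals(fam, scheme_obj, shrinkage, rtm, ref, assume_peak)
        pooled = np.concatenate([res[Sex.MALE], res[Sex.FEMALE]])
        if pooled.size >= 2:
            rows.append(
                {"family_id": fam.family_id,
                 "midparent": model.family_midparent(fam),
                 "residual_sd": float(pooled.std(ddof=1))}
            )
    frame = pd.DataFrame(rows).rename(columns={"residual_sd": "mean_child_diff"})
    if len(frame) < 3:
        raise ValueError("fewer than three families with ≥2 children")
    if frame["midparent"].std() == 0 or frame["mean_child_diff"].std() == 0:
        return FamilyRegressionToMean(frame=frame, r=0.0 if frame["mean_child_diff"].std() == 0 else float("nan"), p_value=float("nan"))
    r, p = stats.pearsonr(frame["midparent"], frame["mean_child_diff"])
    return FamilyRegressionToMean(frame=frame, r=float(r), p_value=float(p))
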