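"""Synthetic nuclear-family cohort generator.

Generates cohorts with the generative structure the analysis assumes, so
that every pipeline stage has a ground truth:

* parents' peak standardized heights are bivariate standard normal with a
  configurable spousal (assortative-mating) correlation;
* each child's standardized peak height is
  ``slope · z_midparent + intercept + ε`` with sex-specific residual SD
  (given in cm and scaled by the reference SD);
* standardized values map to cm through a reference population;
* *measured* heights are peak height minus the age-shrinkage of the
  person's (simulated) age, so the age-correction step has real work to
  undo.

Defaults mirror the study design the analysis code targets: 23 families
of 7–16 adult children, parents aged 62 ± 5 years, midparent slope 0.79,
residual SDs 4.5 cm (sons) / 4.2 cm (daughters).  The generator encodes
no secular trend by default — intergenerational height differences arise
purely from parental shrinkage — but a constant per-generation trend can
be switched on for sensitivity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cohort import Cohort, Family, Member, Role
from .corrections import DEFAULT_SHRINKAGE, AgeShrinkageModel
from .reference import CDC_DERIVED, ReferencePopulation, Sex

__all__ = ["SimulationParams", "simulate_cohort", "ideal_cohort"]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of the synthetic family cohort."""

    n_families: int = 23
    children_range: tuple[int, int] = (7, 16)
    midparent_slope: float = 0.79
    midparent_intercept: float = 0.0        # standardized units
    residual_sd_son: float = 4.5            # cm
    residual_sd_daughter: float = 4.2       # cm
    ref: ReferencePopulation = CDC_DERIVED
    assortative_corr: float = 0.2
    parent_age_mean: float = 62.0
    parent_age_sd: float = 5.0
    child_age_range: tuple[float, float] = (20.0, 45.0)
    shrinkage: AgeShrinkageModel = DEFAULT_SHRINKAGE
    secular_trend: float = 0.0              # cm added to every child's peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        lo, hi = self.children_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("children_range must satisfy 1 <= min <= max <= 20")
        if self.residual_sd_son <= 0 or self.residual_sd_daughter <= 0:
            raise ValueError("residual SDs must be positive")
        if not (0 <= self.assortative_corr < 1):
            raise ValueError("assortative_corr must be in [0, 1)")
        if self.child_age_range[0] < 15:
            raise ValueError("children must be adults (age >= 15)")

    def residual_sd(self, sex: Sex) -> float:
        return self.residual_sd_son if sex is Sex.MALE else self.residual_sd_daughter


def _draw_parent_ages(rng: np.random.Generator, params: SimulationParams, n: int):
    ages = rng.normal(params.parent_age_mean, params.parent_age_sd, size=n)
    # keep parents plausibly older than their adult children
    return np.clip(ages, 40.0, 100.0)


def simulate_cohort(params: SimulationParams = SimulationParams(),
                    seed: Optional[int] = None) -> Cohort:
    """Draw one synthetic cohort; fully reproducible from the seed.

    ``seed`` overrides ``params.seed`` when given.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ref = params.ref
    cov = [[1.0, params.assortative_corr], [params.assortative_corr, 1.0]]
    parent_z = rng.multivariate_normal([0.0, 0.0], cov, size=params.n_families)
    father_ages = _draw_parent_ages(rng, params, params.n_families)
    mother_ages = _draw_parent_ages(rng, params, params.n_families)
    lo, hi = params.children_range
    n_children = rng.integers(lo, hi + 1, size=params.n_families)

    families = []
    for i in range(params.n_families):
        fid = f"fam{i + 1:04d}"
        zf, zm = parent_z[i]
        father_peak = ref.mean_male + zf * ref.sd_male
        mother_peak = ref.mean_female + zm * ref.sd_female
        father = Member(
            person_id=f"{fid}-father", family_id=fid, role=Role.FATHER,
            sex=Sex.MALE, age=float(father_ages[i]),
            height=father_peak - params.shrinkage.shrinkage(father_ages[i], Sex.MALE),
        )
        mother = Member(
            person_id=f"{fid}-mother", family_id=fid, role=Role.MOTHER,
            sex=Sex.FEMALE, age=float(mother_ages[i]),
            height=mother_peak - params.shrinkage.shrinkage(mother_ages[i], Sex.FEMALE),
        )
        z_mp = (zf + zm) / 2.0
        children = []
        for j in range(int(n_children[i])):
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            sd_ref = ref.sd(sex)
            eps = rng.normal(0.0, params.residual_sd(sex) / sd_ref)
            z_child = params.midparent_slope * z_mp + params.midparent_intercept + eps
            peak = ref.mean(sex) + z_child * sd_ref + params.secular_trend
            age = float(rng.uniform(*params.child_age_range))
            children.append(
                Member(
                    person_id=f"{fid}-child{j + 1:02d}", family_id=fid,
                    role=Role.CHILD, sex=sex, age=age,
                    height=peak - params.shrinkage.shrinkage(age, sex),
                )
            )
        families.append(Family(father=father, mother=mother, children=tuple(children)))
    return Cohort(families=tuple(families))


def ideal_cohort(params: SimulationParams = SimulationParams(),
                 seed: Optional[int] = None) -> Cohort:
    """Noise-free fixture: ε ≡ 0 and every age ≤ 30 (no shrinkage).

    Children equal the regression-transformed midparent exactly, so the
    analysis pipeline must recover the generative slope and intercept to
    machine precision and report zero residual scatter.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ref = params.ref
    cov = [[1.0, params.assortative_corr], [params.assortative_corr, 1.0]]
    parent_z = rng.multivariate_normal([0.0, 0.0], cov, size=params.n_families)
    lo, hi = params.children_range
    n_children = rng.integers(lo, hi + 1, size=params.n_families)

    families = []
    for i in range(params.n_families):
        fid = f"fam{i + 1:04d}"
        zf, zm = parent_z[i]
        father = Member(
            person_id=f"{fid}-father", family_id=fid, role=Role.FATHER,
            sex=Sex.MALE, age=28.0, height=ref.mean_male + zf * ref.sd_male,
        )
        mother = Member(
            person_id=f"{fid}-mother", family_id=fid, role=Role.MOTHER,
            sex=Sex.FEMALE, age=28.0, height=ref.mean_female + zm * ref.sd_female,
        )
        z_child = params.midparent_slope * (zf + zm) / 2.0 + params.midparent_intercept
        children = []
        for j in range(int(n_children[i])):
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            children.append(
                Member(
                    person_id=f"{fid}-child{j + 1:02d}", family_id=fid,
                    role=Role.CHILD, sex=sex, age=25.0,
                    height=ref.mean(sex) + z_child * ref.sd(sex),
                )
            )
        families.append(Family(father=father, mother=mother, children=tuple(children)))
    return Cohort(families=tuple(families))
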