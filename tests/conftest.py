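import numpy as np
import pytest

from targetheight import (
    CDC_DERIVED,
    Cohort,
    Family,
    Member,
    Role,
    Sex,
    SimulationParams,
    packaged_growth_chart_path,
    read_reference_table,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cdc_table():
    """Packaged synthetic age-20 growth-chart table (9 percentile rows)."""
    return read_reference_table(packaged_growth_chart_path())


@pytest.fixture(scope="session")
def ref():
    return CDC_DERIVED


@pytest.fixture(scope="session")
def stochastic_cohort():
    """Mid-sized simulated cohort with the default generative parameters."""
    return simulate_cohort(SimulationParams(n_families=200, seed=7))


def make_member(fid, pid, role, sex, age, height):
    return Member(person_id=pid, family_id=fid, role=Role.parse(role),
                  sex=Sex.parse(sex), age=age, height=height)


def make_family(fid, father_h, mother_h, child_specs, parent_age=28.0):
    """child_specs: list of (sex, height) or (sex, height, age)."""
    children = []
    for i, spec in enumerate(child_specs):
        sex, height, *rest = spec
        age = rest[0] if rest else 25.0
        children.append(make_member(fid, f"{fid}-c{i}", "child", sex, age, height))
    return Family(
        father=make_member(fid, f"{fid}-f", "father", "M", parent_age, father_h),
        mother=make_member(fid, f"{fid}-m", "mother", "F", parent_age, mother_h),
        children=tuple(children),
    )
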