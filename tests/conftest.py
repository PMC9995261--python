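import numpy as np
import pytest

from hkcea import make_reference_fixture, run_cohort
from hkcea.parameters import LifeTable, ParameterSet, iter_params


@pytest.fixture(scope="session")
def fixture_params() -> ParameterSet:
    return make_reference_fixture()


@pytest.fixture(scope="session")
def base_runs(fixture_params):
    """Lifetime base-case trajectories for both arms (shared across tests)."""
    a = run_cohort("patiromer", fixture_params)
    b = run_cohort("soc", fixture_params)
    return a, b


def immortal(p: ParameterSet) -> ParameterSet:
    """A copy with all mortality switched off (background and disease)."""
    q = p.model_copy(deep=True)
    n = len(q.life_table.ages)
    q.life_table = LifeTable(ages=q.life_table.ages,
                             qx_female=[0.0] * n, qx_male=[0.0] * n)
    for d in q.ckd.death.values():
        d.mean = 0.0
    for d in q.hf.death.values():
        d.mean = 0.0
    for row in (q.esrd.death_on_dialysis, q.esrd.death_with_transplant):
        for knot in (row.age40, row.age50, row.age60, row.age70):
            knot.mean = 0.0
    return q


def no_esrd(p: ParameterSet) -> ParameterSet:
    """A copy in which nobody can reach dialysis or transplant."""
    q = p.model_copy(deep=True)
    q.ckd.prog_5_to_dialysis.mean = 0.0
    for row in (q.esrd.transplant_from_ckd5, q.esrd.transplant_from_dialysis):
        for knot in (row.age40, row.age50, row.age60, row.age70):
            knot.mean = 0.0
    return q


def fix_all(p: ParameterSet) -> ParameterSet:
    """A copy with every standard error zeroed (degenerate distributions)."""
    q = p.model_copy(deep=True)
    for _, param in iter_params(q):
        param.se = 0.0
    return q


def microsim_se(result, key: str) -> float:
    """Monte-Carlo standard error of a per-individual lifetime total."""
    arr = result.individual[key]
    return float(arr.std(ddof=1) / np.sqrt(arr.size))
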