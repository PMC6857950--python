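import datetime

import numpy as np
import pytest

from wildri.datamodel import AnalyteDefinition, Dataset, SampleRecord
from wildri.synthetic import AnalyteModel, SimulationConfig


def make_sample(animal_id="T1", values=None, date=None, site="SBCP",
                sex="female", age_class="adult", **kw):
    return SampleRecord(
        animal_id=animal_id,
        date=date or datetime.date(2017, 5, 15),
        site=site,
        sex=sex,
        age_class=age_class,
        values=values or {},
        **kw,
    )


def make_dataset(groups, analyte="A", **analyte_kw):
    """Dataset with one analyte: groups is {animal_id: [values]}."""
    samples = [
        make_sample(animal_id=aid, values={analyte: float(v)})
        for aid, vals in groups.items()
        for v in vals
    ]
    return Dataset(samples=samples,
                   analytes=[AnalyteDefinition(analyte, **analyte_kw)])


def one_analyte_config(seed, *, n_single=0, repeats=None, mean=10.0,
                       sd_between=1.0, sd_within=1.0, lognormal=False,
                       floor=None, shifts=None, **demo):
    probs = {
        "site_probs": {"SBCP": 1.0},
        "sex_probs": {"female": 1.0},
        "age_probs": {"adult": 1.0},
        "month_probs": {"May": 1.0},
        "year_probs": {2017: 1.0},
    }
    probs.update(demo)
    return SimulationConfig(
        n_single_animals=n_single,
        repeat_animals=repeats or {},
        analytes={
            "A": AnalyteModel(mean=mean, sd_between=sd_between,
                              sd_within=sd_within, lognormal=lognormal,
                              floor=floor, shifts=shifts or {})
        },
        seed=seed,
        **probs,
    )


def grouped_dataset(group_values, factor="age_class"):
    """Dataset with one analyte and one demographic factor varied."""
    samples = []
    for gi, (level, vals) in enumerate(group_values.items()):
        for j, v in enumerate(vals):
            kw = {factor: level} if factor in ("site", "sex", "age_class") else {}
            s = SampleRecord(
                animal_id=f"g{gi}_{j}",
                date=datetime.date(
                    2017 if factor != "year" else int(level),
                    5 if factor != "month" else
                    {"May": 5, "June": 6, "July": 7, "August": 8}[level],
                    1 + j % 28,
                ),
                site=kw.get("site", "SBCP"),
                sex=kw.get("sex", "female"),
                age_class=kw.get("age_class", "adult"),
                values={"A": float(v)},
            )
            samples.append(s)
    return Dataset(samples=samples,
                   analytes=[AnalyteDefinition("A", nonnegative=False)])


@pytest.fixture(scope="session")
def study_dataset():
    from wildri.synthetic import default_study_config, simulate

    return simulate(default_study_config(1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
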