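import dataclasses
import datetime as dt

import pytest

import mnhsim as m


@pytest.fixture(scope="session")
def params():
    return m.generate_default_parameters(seed=0)


@pytest.fixture()
def woman(params):
    [w] = [p for p in m.make_fixture_population(200, seed=3, params=params)
           if p.sex == "F" and 20 <= p.age_years(dt.date(2023, 1, 1)) <= 35][:1]
    w._age_now = w.age_years(dt.date(2023, 1, 1))
    w.risk_flags.clear()
    return w


def pregnant(woman, gest_days=0):
    woman.is_pregnant = True
    woman.gestational_age = gest_days
    return woman


@pytest.fixture(scope="session")
def directionality_experiment(params):
    """Paired reduced-scale runs of SQ vs all-services-min vs all-services-max.

    Population ~7k, 4 paired runs, 2021-2028 horizon with the intervention
    switching on 1/1/2023; shared per-run seeds give common random numbers
    across scenarios.  Session-scoped: this is the expensive fixture.
    """
    cfg = m.SimulationConfig(population_size=7000,
                             start=dt.date(2021, 1, 1), end=dt.date(2028, 1, 1),
                             runs=4, base_seed=42)
    results = {}
    for name in ("SQ", "All services min.", "All services max."):
        results[name] = m.run_simulation(dataclasses.replace(cfg, scenario=name),
                                         params=params)
    return results
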