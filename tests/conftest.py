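import numpy as np
import pandas as pd
import pytest

from zdexemplar.io import load_study_fixture, to_no_dtp
from zdexemplar.metrics import change_metrics, country_year_metrics, fixture_metrics
from zdexemplar.simulate import SyntheticSpec, generate_study


@pytest.fixture(scope="session")
def study_fixture():
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_metrics(study_fixture):
    return fixture_metrics(study_fixture)


@pytest.fixture(scope="session")
def study_changes(study_metrics):
    return change_metrics(study_metrics, 2000, 2019)


@pytest.fixture(scope="session")
def synthetic_study():
    """A moderate-noise study with a designed exemplar (12 countries)."""
    spec = SyntheticSpec(
        n_countries=12, n_units_range=(8, 120), designated_exemplar=True, seed=42
    )
    panel, truth = generate_study(spec)
    return panel, truth


@pytest.fixture(scope="session")
def synthetic_metrics(synthetic_study):
    panel, _ = synthetic_study
    return country_year_metrics(to_no_dtp(panel))


@pytest.fixture()
def tiny_panel():
    """A hand-written 2-country, 2-year coverage panel."""
    rows = []
    for code, units, cov0 in (("AAA", ["u1", "u2", "u3"], 80.0), ("BBB", ["v1", "v2"], 60.0)):
        for year in (2000, 2001):
            for i, u in enumerate(units):
                rows.append(
                    {
                        "country_code": code,
                        "admin1_id": f"{code}-s0",
                        "admin2_id": u,
                        "year": year,
                        "dtp1_coverage": cov0 + 5 * i + (year - 2000),
                        "population": 1000 * (i + 1),
                    }
                )
    return pd.DataFrame(rows)


def sorted_interpolation_quantile(values, q):
    """Independent oracle: sort and linearly interpolate order statistics."""
    s = np.sort(np.asarray(values, dtype=float))
    n = len(s)
    if n == 1:
        return float(s[0])
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo + 1 >= n:
        return float(s[-1])
    return float(s[lo] * (1 - frac) + s[lo + 1] * frac)
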