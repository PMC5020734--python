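import numpy as np
import pandas as pd
import pytest

import coraldemog as cd


@pytest.fixture
def scheme():
    return cd.SizeClassScheme()


@pytest.fixture
def structure():
    return cd.LifeCycleStructure.default_graph()


@pytest.fixture
def true_matrix(structure):
    return cd.generate_true_matrix(structure, survival_cap=0.95, seed=12345)


@pytest.fixture
def decomp(true_matrix):
    return cd.decompose(true_matrix)


@pytest.fixture
def forecast_config(decomp, scheme):
    return cd.ForecastConfig(
        decomp=decomp,
        dd=cd.DensityDependence(),
        n0=np.array([60.0, 30.0, 20.0, 10.0, 5.0]),
        recruitment=cd.RecruitmentSpec(),
        scheme=scheme,
        horizon=100,
    )


def make_survey_frame(scheme, rows):
    """rows: (year, stratum, transects, counts) tuples -> survey DataFrame."""
    cols = scheme.column_names()
    records = []
    for year, stratum, transects, counts in rows:
        rec = {"year": year, "stratum": stratum, "transects": transects,
               "unit": "raw", "imputed": False}
        rec.update(dict(zip(cols, counts)))
        records.append(rec)
    return pd.DataFrame(records,
                        columns=["year", "stratum", "transects", *cols,
                                 "unit", "imputed"])


@pytest.fixture
def survey_2010(scheme):
    # the two worked 2010 survey rows: 33 colonies at 2 m, 69 at 4 m,
    # three transects each
    return make_survey_frame(scheme, [
        (2010, "2m", 3, (12, 9, 7, 3, 2)),   # total 33
        (2010, "4m", 3, (20, 18, 16, 9, 6)),  # total 69
    ])
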