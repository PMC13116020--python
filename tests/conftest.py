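import numpy as np
import pandas as pd
import pytest

from twingem.data import CANONICAL_COLUMNS, TwinCohort


def make_cohort(pairs, phenotype="walkability", zygosity=None, **extra):
    """Build a TwinCohort from an (n, 2) array of co-twin phenotype values.

    ``zygosity`` is a scalar or per-pair sequence; NaN in the second column
    drops that twin (singleton pair).
    """
    pairs = np.asarray(pairs, float)
    n = len(pairs)
    if zygosity is None:
        zygosity = ["MZ"] * n
    elif isinstance(zygosity, str):
        zygosity = [zygosity] * n
    rows = []
    for i in range(n):
        for j in range(2):
            if j == 1 and np.isnan(pairs[i, 1]) and not extra.get("keep_nan_twin2"):
                continue
            row = {
                "person_id": f"p{i:04d}_{j + 1}",
                "pair_id": f"fam{i:04d}",
                "zygosity": zygosity[i],
                "sex": "female",
                "age": 40.0,
                "bmi": 25.0,
                "walkability": 40.0,
                "work_employed": 1.0,
                "edu_high": 1.0,
                "lives_with_partner": 1.0,
                "deprivation_z": 0.0,
            }
            row[phenotype] = pairs[i, j]
            rows.append(row)
    df = pd.DataFrame(rows)[list(CANONICAL_COLUMNS)]
    return TwinCohort(df)


def make_bivariate_cohort(m_pairs, t_pairs, zygosity):
    """Cohort with both walkability (moderator) and bmi (trait) per twin."""
    m_pairs = np.asarray(m_pairs, float)
    t_pairs = np.asarray(t_pairs, float)
    rows = []
    for i in range(len(m_pairs)):
        for j in range(2):
            rows.append(
                {
                    "person_id": f"p{i:04d}_{j + 1}",
                    "pair_id": f"fam{i:04d}",
                    "zygosity": zygosity[i] if not isinstance(zygosity, str) else zygosity,
                    "sex": "female",
                    "age": 40.0,
                    "walkability": m_pairs[i, j],
                    "bmi": t_pairs[i, j],
                    "work_employed": 1.0,
                    "edu_high": 1.0,
                    "lives_with_partner": 1.0,
                    "deprivation_z": 0.0,
                }
            )
    df = pd.DataFrame(rows)[list(CANONICAL_COLUMNS)]
    return TwinCohort(df)


@pytest.fixture
def four_row_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(
        "person_id,pair_id,zygosity,sex,age,bmi,walkability,"
        "work_employed,edu_high,lives_with_partner,deprivation_z\n"
        "a1,f1,MZ,female,41.2,24.5,43.0,1,1,1,0.2\n"
        "a2,f1,MZ,female,41.2,26.1,45.5,1,0,1,0.2\n"
        "b1,f2,DZ,male,38.9,28.0,39.0,1,1,0,-0.4\n"
        "b2,f2,DZ,female,38.9,22.3,51.2,0,1,1,-0.1\n"
    )
    return path
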