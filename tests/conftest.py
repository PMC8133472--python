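import numpy as np
import pandas as pd
import pytest

from mosaicdiv import (
    GeneratorParams,
    OccurrenceMatrix,
    Survey,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Five-region synthetic dataset shared across read-only tests."""
    params = GeneratorParams(n_regions=5, seed=11)
    return generate_dataset(params)


@pytest.fixture()
def toy_tables(tmp_path):
    """3-survey x 4-species toy CSV triple on disk."""
    occ = pd.DataFrame(
        [[1, 0, 1, 0], [0, 0, 0, 1], [1, 1, 1, 0]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB", "spC", "spD"],
    )
    occ.index.name = "survey_id"
    occ_path = tmp_path / "occurrence.csv"
    occ.to_csv(occ_path)

    surveys = pd.DataFrame(
        {
            "survey_id": ["s1", "s2", "s3"],
            "lon": [0.0, 0.1, 0.2],
            "lat": [0.0, 0.1, 0.2],
            "protection": ["SPA", "NPA", "RA"],
            "pa_id": ["pa1", "", "pa2"],
            "temp": [10.0, 11.0, 12.0],
        }
    )
    surv_path = tmp_path / "surveys.csv"
    surveys.to_csv(surv_path, index=False)

    species = pd.DataFrame(
        {"species_id": ["spA", "spB", "spC", "spD"], "iucn": ["LC", "EN", "", "DD"]}
    )
    sp_path = tmp_path / "species.csv"
    species.to_csv(sp_path, index=False)
    return occ_path, surv_path, sp_path


def make_occ(rows, surveys=None, species=None):
    rows = np.asarray(rows)
    surveys = surveys or [f"s{i}" for i in range(rows.shape[0])]
    species = species or [f"sp{j}" for j in range(rows.shape[1])]
    return OccurrenceMatrix(pd.DataFrame(rows, index=surveys, columns=species))


def make_survey(sid, lon=0.0, lat=0.0, protection="NPA", pa_id=None, env=None):
    return Survey(
        survey_id=sid,
        lon=lon,
        lat=lat,
        protection=protection,
        pa_id=pa_id,
        env=env or {},
    )
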