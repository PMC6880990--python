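import math

import pandas as pd
import pytest

from phedas.vocab import load_concept_tables, load_phecode_map, toy_data_path


@pytest.fixture(scope="session")
def toy_map():
    return load_phecode_map(toy_data_path("toy_phecode_map.csv"))


@pytest.fixture(scope="session")
def concept_tables():
    return load_concept_tables(
        toy_data_path("toy_icd9_cui.csv"), toy_data_path("toy_cui_strings.csv")
    )


@pytest.fixture()
def depression_map(tmp_path):
    """Three ICD-9 codes grouping into the depression phecode 296.2."""
    path = tmp_path / "map.csv"
    path.write_text(
        "icd9,phecode,phecode_label\n"
        "296.21,296.2,Depression\n"
        "296.31,296.2,Depression\n"
        "311,296.2,Depression\n"
    )
    return load_phecode_map(path)


@pytest.fixture()
def hand_visits():
    """Three subjects, two phecodes worth of codes, fully hand-traceable."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "a", "b", "b", "c"],
            "age_at_visit": [40.0, 42.5, 41.0, 50.0, 50.5, 30.0],
            "icd9": ["296.21", "311", "331.0", "331.0", "331.0", "296.31"],
        }
    )


@pytest.fixture()
def log_or():
    return math.log
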