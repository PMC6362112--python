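import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from casepop.tables_io import CaseRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(**kwargs) -> CaseRecord:
    base = dict(subject_id="s1", sex="male", birth_year=1890)
    base.update(kwargs)
    return CaseRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def full_records():
    """Ten men born 1879-1913 with every field present."""
    rows = []
    for i in range(10):
        rows.append(
            CaseRecord(
                subject_id=f"s{i}",
                sex="male",
                birth_year=1880 + 3 * i,
                birth_month=(i % 12) + 1,
                urban_birth=i % 2 == 0,
                born_abroad=i % 5 == 0,
                paternal_age=25 + 2 * i,
                maternal_age=22 + 2 * i,
                birth_rank=(i % 3) + 1,
                sibship_size=(i % 3) + 2,
            )
        )
    return rows


@pytest.fixture
def case_csv(tmp_path):
    """A small well-formed case table on disk, with some empty cells."""
    path = tmp_path / "cases.csv"
    path.write_text(
        "subject_id,sex,birth_year,birth_month,urban_birth,birthplace_population,"
        "born_abroad,paternal_age,maternal_age,birth_rank,sibship_size\n"
        "a,male,1885,2,true,5000,false,34,30,1,3\n"
        "b,male,1900,,false,150,,41,36,2,4\n"
        "c,female,1910,7,,,true,,,,\n"
    )
    return path
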