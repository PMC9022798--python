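import pytest
from hypothesis import settings

from fuzzydelphi import datasets

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return datasets.load_catalog()


@pytest.fixture(scope="session")
def round1_table():
    return datasets.load_round1_results()


@pytest.fixture(scope="session")
def round2_table():
    return datasets.load_round2_results()


@pytest.fixture()
def responses_csv(tmp_path):
    """Write a small canonical responses file; returns its path."""

    def write(rows, header="round,expert_id,specialty,years_experience,indicator_id,rating,comment"):
        path = tmp_path / "responses.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
        return path

    return write
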