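from pathlib import Path

import pytest

from qtap.tables_io import read_protein_groups, read_sample_design

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_paths():
    return {
        "protein_groups": DATA / "proteinGroups_20.tsv",
        "design": DATA / "design_4v4.tsv",
    }


@pytest.fixture(scope="session")
def design_4v4(fixture_paths):
    return read_sample_design(fixture_paths["design"], bait_id="SMXL7")


@pytest.fixture()
def fixture_table(fixture_paths, design_4v4):
    return read_protein_groups(fixture_paths["protein_groups"], "lfq", design_4v4)
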