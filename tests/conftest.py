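import pytest

from ppievo import build_roster, default_design_config


@pytest.fixture(scope="session")
def paper_design():
    """The default five-species x 11-gene roster (53 proteins)."""
    return build_roster(default_design_config())


@pytest.fixture()
def tiny_design():
    """2 genes x 3 species with one absence: 5 proteins."""
    return build_roster(
        {
            "species": ["S1", "S2", "S3"],
            "genes": ["gA", "gB"],
            "absences": [["gB", "S3"]],
            "divergence_my": {
                "S1": {"S1": 0, "S2": 10, "S3": 30},
                "S2": {"S1": 10, "S2": 0, "S3": 30},
                "S3": {"S1": 30, "S2": 30, "S3": 0},
            },
        }
    )
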