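"""Shared fixtures: small truth-known synthetic studies."""

import pytest
from hypothesis import settings

from snpqc.fixtures import SnpSpec, generate_truth, inject_defects, write_fixture
from snpqc.study import create_study

settings.register_profile("snpqc", derandomize=True, deadline=None)
settings.load_profile("snpqc")


@pytest.fixture(scope="session")
def clean_truth():
    """Defect-free study: 60 samples, two SNPs, 10% replicates."""
    return generate_truth(
        60,
        [SnpSpec("rs328", ("A", "G"), 0.3), SnpSpec("rs111", ("C", "T"), 0.15)],
        replicate_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def defect_truth():
    """200-sample single-SNP study with every defect type injected."""
    truth = generate_truth(
        200, [SnpSpec("rs328", ("A", "G"), 0.3)], replicate_fraction=0.1, seed=42
    )
    return inject_defects(
        truth, k_discordant=3, k_nocall=5, k_unknown_ids=2, k_absent=1, seed=42
    )


@pytest.fixture()
def sds_fixture(tmp_path, defect_truth):
    """The defect study written as SDS plate files."""
    return write_fixture(defect_truth, "SDS", path=tmp_path / "sds")


@pytest.fixture()
def typer_fixture(tmp_path, defect_truth):
    """The defect study written as one multiplexed TYPER file."""
    return write_fixture(defect_truth, "TYPER", path=tmp_path / "typer")


@pytest.fixture()
def defect_study(sds_fixture, defect_truth):
    return create_study("demo", sds_fixture.manifest, expected_replicate_count=20)
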