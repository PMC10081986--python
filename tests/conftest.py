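import pytest

from ipoc.hprint import Calibration, run_pipeline
from ipoc.sample_io import BiomarkerSample
from ipoc.synthetic_data import SyntheticConfig, generate_samples


@pytest.fixture
def cal() -> Calibration:
    return Calibration()


@pytest.fixture
def make_sample():
    """Factory for BiomarkerSample with sensible defaults."""

    def _make(
        sample_id="S1",
        ip25=1.0,
        hbi2=1.0,
        hbi3=1.0,
        species="Boreogadus saida",
        taxon_group="fish",
        habitat="mixed",
        latitude=71.0,
        year=2015,
        month=7,
        **kw,
    ) -> BiomarkerSample:
        return BiomarkerSample(
            sample_id=sample_id,
            species=species,
            taxon_group=taxon_group,
            habitat=habitat,
            latitude=latitude,
            year=year,
            month=month,
            ip25=ip25,
            hbi2=hbi2,
            hbi3=hbi3,
            **kw,
        )

    return _make


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw from the default study-shaped generator (n=2000)."""
    samples, truth = generate_samples(SyntheticConfig(n_samples=2000, seed=42))
    results, excluded = run_pipeline(samples)
    return samples, truth, results, excluded
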