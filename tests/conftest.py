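import pytest

import omicslink as ol


@pytest.fixture(scope="session")
def reference_table():
    """The bundled 15-pair same-trend salinity-response set."""
    return ol.load_same_trend_reference()


@pytest.fixture(scope="session")
def reference_inputs():
    """(transcripts, proteins, blast hits) expanded from the reference set."""
    return ol.reference_pipeline_inputs()


@pytest.fixture(scope="session")
def reference_result(reference_inputs):
    transcripts, proteins, hits = reference_inputs
    return ol.run_pipeline(transcripts, proteins, hits)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (fixed seed)."""
    return ol.generate_dataset(ol.SimulationConfig(seed=1))
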