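import pytest

from enhancerlink import pipeline, synth


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The default synthetic scenario at full library depth (seed 42)."""
    out = tmp_path_factory.mktemp("scenario_default")
    return synth.make_scenario(out, name="default", seed=42, n_pairs=100_000)


@pytest.fixture(scope="session")
def pipeline_result(default_scenario):
    """Full pipeline run over the default scenario's on-disk files."""
    return pipeline.run_from_scenario_dir(default_scenario.out_dir)


@pytest.fixture()
def small_refs():
    from enhancerlink.fragmap import ReferenceSet

    return ReferenceSet(
        {
            "c1": "AACCGGATCTTACGTACCAGATCAATT",
            "c2": "TTTTGATCGGGG",
        }
    )
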