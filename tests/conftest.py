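import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_sized_run(tmp_path_factory):
    """One full pipeline run on the study-sized synthetic panel.

    9 benign controls, 14 pathogenic controls, 54 query variants; 3
    replicates at 10,000 reads/sample. Shared across tests that inspect
    different facets of the same run.
    """
    from crisprselect import pipeline

    out = tmp_path_factory.mktemp("paper_run")
    config = {
        "mode": "simulate",
        "seed": 20,
        "out_dir": str(out),
        "simulate": {
            "n_benign_controls": 9,
            "n_pathogenic_controls": 14,
            "n_query": 54,
            "n_reads_per_sample": 10_000,
            "n_replicates": 3,
        },
    }
    return config, pipeline.run_pipeline(config)
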