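import pytest

from cernax.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort at seed 1 (53 tumors, 13 normals)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def small_config():
    """A fast cohort configuration for serialization/round-trip tests."""
    return CohortConfig(
        n_tumor=12,
        n_paired_normal=6,
        n_olnm_pos=4,
        n_lncrna=20,
        n_pcg=60,
        n_mirna=10,
        n_true_axes=1,
        n_decoys_per_class=1,
        lncrna_len=300,
        utr_len=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_pipeline_outdir(tmp_path_factory):
    """Full pipeline run on the default seed-1 cohort (shared, read-only)."""
    from cernax.config import PipelineConfig
    from cernax.pipeline import run_all

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(
        seed=1, outdir=str(outdir), simulate=CohortConfig(seed=1),
        log_level="WARNING",
    )
    run_all(cfg)
    return outdir
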