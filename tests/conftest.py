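import pytest

from t2tcurate import simgenome as sg


@pytest.fixture(scope="session")
def small_config() -> sg.SimConfig:
    """A compact diploid genome: 2 macro + 3 micro + Z/W, all features on."""
    return sg.SimConfig(
        seed=11,
        n_macro=2,
        n_micro=3,
        macro_len_range=(2_500_000, 3_500_000),
        micro_len_range=(1_200_000, 1_800_000),
        satellite_specs=[
            sg.SatelliteSpec(98, 300, "macro1", 900_000),
            sg.SatelliteSpec(398, 120, "macro2", 700_000),
        ],
        z_len=1_600_000,
        w_len=2_100_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sg.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return small_genome[2]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """On-disk fixture set written once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = sg.write_fixtures(outdir, small_config)
    return outdir, manifest
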