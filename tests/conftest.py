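import pytest

from herbtrends import synthetic_data as sd


@pytest.fixture
def tiny_config():
    """Two small crops, deterministic, no noise."""
    return sd.SimulationConfig(
        seed=7,
        crops=(
            sd.CropPlan("maize", (1990, 1991, 1992, 1993, 1994), n_ais=3, n_labels_per_ai=2,
                        at_baseline=1.0, at_slope=0.05),
            sd.CropPlan("rice", (1990, 1995, 2000), n_ais=2, n_labels_per_ai=1,
                        at_baseline=2.0, at_slope=0.07, dominance_weights=(0.8, 0.2)),
        ),
    )


@pytest.fixture
def tiny_dataset(tiny_config):
    return sd.generate(tiny_config)


@pytest.fixture
def tiny_run(tiny_dataset, tmp_path):
    """Tables written to disk plus a loadable run configuration."""
    from herbtrends.cli_report import load_run_config

    paths = sd.write_dataset(tiny_dataset, tmp_path / "sim")
    return tiny_dataset, paths, load_run_config(paths["run_config"])
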