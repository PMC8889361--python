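import pytest

from cwsipy import PipelineConfig, default_scenario, run_pipeline
from cwsipy.synthetic import (
    BaselineTruth,
    CultivarTruth,
    RegimeTruth,
    ScenarioConfig,
)


def small_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """One cultivar-year, two replicates: fast but exercises every stage."""
    kwargs = dict(
        cultivars=[
            CultivarTruth(
                label="Goldasht",
                baselines={"2017": BaselineTruth(-0.85, 0.75, 7.8)},
                base_water_mm={"2017": 570.3},
            )
        ],
        regimes=[
            RegimeTruth("well_watered", 1.00, 0.205),
            RegimeTruth("mild", 0.75, 0.3025),
            RegimeTruth("severe", 0.50, 0.6125),
            RegimeTruth("most_severe", 0.25, 0.70),
            RegimeTruth("unirrigated", None, 1.0),
        ],
        years=["2017"],
        n_replicates=2,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the study-shaped default scenario."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(
        PipelineConfig(outdir=outdir, scenario=default_scenario(seed=0), seed=0)
    )
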