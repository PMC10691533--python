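"""Shared fixtures: the default synthetic study and one full pipeline run.

The expensive artifacts (fixture generation, two end-to-end pipeline runs for
the determinism check) are session-scoped so every test reuses them.
"""

from pathlib import Path

import pytest

import panconet as pc

SEED = 1
COHORTS = ["C1", "C2", "C3"]


@pytest.fixture(scope="session")
def sim_config() -> pc.SimulationConfig:
    return pc.default_config(seed=SEED)


@pytest.fixture(scope="session")
def bundle(sim_config):
    return pc.generate_all(sim_config)


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("fixture")
    pc.write_fixture(bundle, d)
    cfg = pc.PipelineConfig(apply_log2=False, min_aggregation_weight=3,
                            seed=SEED, input_dir=str(d))
    cfg.to_yaml(d / "pipeline.yaml")
    return d


@pytest.fixture(scope="session")
def pipeline_outputs(fixture_dir) -> tuple[Path, Path]:
    """Two CLI runs of `panconet all` with the same seed (determinism)."""
    from click.testing import CliRunner
    from panconet.cli import main

    runner = CliRunner()
    outs = []
    for name in ("run_a", "run_b"):
        out = fixture_dir / name
        result = runner.invoke(main, [
            "all", "--config", str(fixture_dir / "pipeline.yaml"),
            "--input-dir", str(fixture_dir), "--out", str(out),
            "--seed", str(SEED)])
        assert result.exit_code == 0, result.output
        outs.append(out)
    return tuple(outs)


@pytest.fixture(scope="session")
def run_dir(pipeline_outputs) -> Path:
    return pipeline_outputs[0]


@pytest.fixture(scope="session")
def hierarchies(run_dir):
    from panconet.pipeline import _read_module_table
    return {label: _read_module_table(run_dir / f"{label}.modules.tsv")
            for label in COHORTS}
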