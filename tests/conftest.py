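import json
from pathlib import Path

import pytest

from tsnet import fixtures as fx
from tsnet import pipeline as pl


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle (seed 7), shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    return fx.generate_fixture(fx.FixtureConfig(seed=7), out)


def make_run_config(bundle, out_dir) -> pl.RunConfig:
    p = bundle.paths
    return pl.RunConfig(
        genome=str(p["genome"]),
        gtf=str(p["gtf"]),
        expression=str(p["expression"]),
        pwms=str(p["pwms"]),
        sf_motifs=str(p["sf_motifs"]),
        conservation=str(p["conservation"]),
        gene_sets=str(p["gene_sets"]),
        out_dir=str(out_dir),
        seed=bundle.config.seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run on the shared bundle."""
    out = tmp_path_factory.mktemp("run")
    cfg = make_run_config(bundle, out)
    report = pl.run_pipeline(cfg)
    return cfg, report


@pytest.fixture(scope="session")
def truth(bundle):
    return json.loads(Path(bundle.paths["truth"]).read_text())
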