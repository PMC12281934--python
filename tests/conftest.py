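from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ribobound import PipelineConfig, run_all
from ribobound.simulate import SimulationConfig, make_benchmark

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bench60(tmp_path_factory):
    """A 60-leaf synthetic benchmark, shared across the session."""
    out = tmp_path_factory.mktemp("bench60")
    cfg = SimulationConfig(n_leaves=60, seed=7)
    return make_benchmark(cfg, out)


@pytest.fixture(scope="session")
def pipeline60(bench60, tmp_path_factory):
    """Full pipeline result (with tree) on the 60-leaf benchmark."""
    out = tmp_path_factory.mktemp("out60")
    cfg = PipelineConfig(
        fasta=bench60.fasta,
        taxonomy=bench60.taxonomy,
        tree=bench60.newick,
        out_dir=out,
        n_chunks=13,
    )
    return run_all(cfg)


def make_taxonomy(strain_id: str, **over):
    """A TaxonomyRecord with defaults, for compact test data."""
    from ribobound import TaxonomyRecord

    fields = dict(
        strain_id=strain_id,
        domain="Bacteria",
        phylum="p1",
        class_="c1",
        order="o1",
        family="f1",
        genus="g1",
        species="sp1",
    )
    fields.update(over)
    return TaxonomyRecord(**fields)
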