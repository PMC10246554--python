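import glob

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pocketmap import pipeline, synthgen
from pocketmap.seqmodel import DomainAnnotation, ProteinRecord


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete synthetic input bundle (defaults, seed 3) plus truth."""
    out = tmp_path_factory.mktemp("bundle")
    config = synthgen.SimConfig(seed=3)
    truth = synthgen.generate_bundle(config, out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_result(small_bundle, tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("run")
    bundle, truth = small_bundle
    config = pipeline.RunConfig(
        proteins=bundle / "proteins.fasta",
        domains=bundle / "domains.tsv",
        evidence=sorted(glob.glob(str(bundle / "evidence_*.tsv"))),
        structures=bundle / "structures",
        out_dir=out_dir,
    )
    return pipeline.run_pipeline(config), truth


@pytest.fixture
def toy_protein():
    return ProteinRecord(
        protein_id="TOY1",
        sequence="MKYAKCCDEFGHILMNPQRSTVWYAAKR",
        domains=[
            DomainAnnotation("C1A", 2, 6),
            DomainAnnotation("DAGKc", 10, 20),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
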