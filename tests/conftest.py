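import random

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dualindex import RunConfig, run_pipeline
from dualindex.primer_assembly import load_templates


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def default_result(tmp_path_factory):
    """One full default run (k=8, three plates per role) shared by the
    suite; the pipeline's own validate_run has already audited it."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(RunConfig(output_dir=outdir))


@pytest.fixture(scope="session")
def single_plate_runs(tmp_path_factory):
    """The same one-plate configuration executed twice with one seed, for
    determinism checks; returns the two output directories."""
    dirs = []
    for tag in ("a", "b"):
        outdir = tmp_path_factory.mktemp(f"rerun_{tag}")
        run_pipeline(RunConfig(n_plates=1, seed=42, output_dir=outdir))
        dirs.append(outdir)
    return dirs


@pytest.fixture
def rng():
    return random.Random(1234)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
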