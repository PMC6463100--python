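import pytest

from ampvar import RunSimConfig, simulate_run_dir


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """A noise-free toy dataset: 4 SNPs + 1 homopolymer deletion, 6 combos."""
    outdir = tmp_path_factory.mktemp("toy")
    manifest = simulate_run_dir(outdir, RunSimConfig(seed=11))
    return manifest
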