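import pytest

from loopscape.synthetic import SimConfig, generate


SMALL_CONFIG_KWARGS = dict(
    chrom_sizes={"chr1": 3_000_000, "chr2": 2_000_000},
    n_loops={"intra": 10, "inter": 5, "one_anchor": 3, "not_in_tad": 2},
    n_genes=60,
    n_crystallin=4,
    n_peaks_epi_only=5,
    n_peaks_fib_only=5,
    n_peaks_shared=5,
    seed=1,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small generated feature universe shared across tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(**SMALL_CONFIG_KWARGS)
    truth = generate(cfg, outdir)
    return cfg, truth, outdir
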