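import numpy as np
import pytest

from hicqc import (
    LINKER19,
    GenomeSpec,
    SimulationConfig,
    SimulatedLibrary,
    extract_pairs,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    """Two 100 kb chromosomes shared by most simulation tests."""
    return generate_genome(GenomeSpec(n_chromosomes=2, chrom_length=100_000, seed=7))


@pytest.fixture(scope="session")
def medium_genome():
    """Two 1 Mb chromosomes for larger statistical checks."""
    return generate_genome(GenomeSpec(n_chromosomes=2, chrom_length=1_000_000, seed=7))


@pytest.fixture(scope="session")
def sim_library(medium_genome, tmp_path_factory):
    """A mixed 20k-pair library with adapter and injected duplicates.

    Returns (library, paths dict) with FASTQ/SAM/truth written once for the
    whole session.
    """
    cfg = SimulationConfig(
        n_pairs=20_000,
        seed=11,
        adapter_sequences=(LINKER19.sequence,),
        adapter_ligation_freq=0.5,
        duplicate_fraction=0.03,
    )
    lib = SimulatedLibrary(cfg, medium_genome)
    outdir = tmp_path_factory.mktemp("sim_library")
    paths = lib.write_all(str(outdir), gzip_fastq=False)
    return lib, paths


@pytest.fixture(scope="session")
def sim_pairs(sim_library):
    """Extraction output for the shared library."""
    _, paths = sim_library
    return extract_pairs(paths["sam"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
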